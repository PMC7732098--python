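fish_id,video_id,entry_time,exit_time,taxon
V1_F0000,V1,179.879,180.423,gadoid
V1_F0001,V1,184.776,188.577,gadoid
V1_F0002,V1,158.608,161.616,gadoid
V1_F0003,V1,61.046,67.03,gadoid
V1_F0004,V1,108.102,108.802,gadoid
V1_F0005,V1,27.51,32.012,gadoid
V1_F0006,V1,68.312,68.688,gadoid
V1_F0007,V1,84.179,85.931,gadoid
V1_F0008,V1,264.709,269.21,gadoid
V1_F0009,V1,14.965,17.186,gadoid
V1_F0010,V1,208.789,213.316,gadoid
V1_F0011,V1,136.302,136.653,gadoid
V1_F0012,V1,217.426,219.974,gadoid
V1_F0013,V1,19.978,20.313,gadoid
V1_F0014,V1,82.188,84.318,gadoid
V1_F0015,V1,130.906,135.054,gadoid
V1_F0016,V1,83.189,83.605,gadoid
V1_F0017,V1,1.949,7.111,gadoid
V1_F0018,V1,15.805,19.588,gadoid
V1_F0019,V1,247.048,250.159,gadoid
V1_F0020,V1,90.523,91.241,gadoid
V1_F0021,V1,286.255,289.332,gadoid
V1_F0022,V1,51.246,52.037,gadoid
V1_F0023,V1,278.309,282.162,gadoid
V1_F0024,V1,285.655,287.463,gadoid
V1_F0025,V1,127.421,127.784,gadoid
V1_F0026,V1,3.655,10.902,gadoid
V1_F0027,V1,123.184,124.447,gadoid
V1_F0028,V1,7.587,7.848,gadoid
V1_F0029,V1,31.566,32.465,gadoid
V1_F0030,V1,298.739,300.0,gadoid
V1_F0031,V1,60.734,61.088,gadoid
V1_F0032,V1,151.725,152.838,gadoid
V1_F0033,V1,266.905,267.962,gadoid
V1_F0034,V1,83.76,85.67,gadoid
V1_F0035,V1,274.927,277.576,gadoid
V1_F0036,V1,39.703,40.666,gadoid
V1_F0037,V1,199.14,200.925,gadoid
V1_F0038,V1,201.87,205.188,gadoid
V1_F0039,V1,228.347,230.198,gadoid
V1_F0040,V1,132.805,135.193,gadoid
V1_F0041,V1,161.329,166.343,gadoid
V1_F0042,V1,145.436,147.462,gadoid
V1_F0043,V1,23.763,24.791,gadoid
V1_F0044,V1,108.947,109.857,gadoid
V1_F0045,V1,241.622,242.731,gadoid
V1_F0046,V1,229.783,231.221,gadoid
V1_F0047,V1,110.878,111.229,gadoid
V1_F0048,V1,131.415,131.673,gadoid
V1_F0049,V1,208.222,210.852,gadoid
V1_F0050,V1,207.117,209.674,gadoid
V1_F0051,V1,244.78,245.555,gadoid
V1_F0052,V1,252.062,253.138,gadoid
V1_F0053,V1,202.389,206.806,gadoid
V1_F0054,V1,297.139,300.0,gadoid
V1_F0055,V1,55.175,62.004,gadoid
V1_F0056,V1,78.21,78.749,gadoid
V1_F0057,V1,5.5,14.832,gadoid
V1_F0058,V1,146.413,147.274,gadoid
V1_F0059,V1,69.955,73.952,gadoid
V1_F0060,V1,289.743,291.827,gadoid
V1_F0061,V1,37.609,43.061,gadoid
V1_F0062,V1,83.542,85.246,gadoid
V1_F0063,V1,157.289,160.127,gadoid
V1_F0064,V1,220.514,221.527,gadoid
V1_F0065,V1,299.897,300.0,gadoid
V1_F0066,V1,14.915,15.382,gadoid
V1_F0067,V1,189.023,190.203,gadoid
V1_F0068,V1,213.0,213.819,gadoid
V1_F0069,V1,165.277,167.085,gadoid
V1_F0070,V1,249.714,252.724,gadoid
V1_F0071,V1,7.028,7.841,gadoid
V1_F0072,V1,21.719,24.994,gadoid
V1_F0073,V1,242.076,242.958,gadoid
V1_F0074,V1,232.997,237.111,gadoid
V1_F0075,V1,188.591,190.379,gadoid
V1_F0076,V1,93.67,94.985,gadoid
V1_F0077,V1,221.404,229.312,gadoid
V1_F0078,V1,92.631,93.012,gadoid
V1_F0079,V1,201.781,203.15,gadoid
V1_F0080,V1,73.881,74.258,gadoid
V1_F0081,V1,78.832,80.08,gadoid
V1_F0082,V1,235.864,240.092,gadoid
V1_F0083,V1,211.825,214.533,gadoid
V1_F0084,V1,265.295,268.237,gadoid
V1_F0085,V1,63.717,64.734,gadoid
V1_F0086,V1,154.494,154.757,gadoid
V1_F0087,V1,161.244,162.582,gadoid
V1_F0088,V1,191.793,195.013,gadoid
V1_F0089,V1,96.843,97.336,gadoid
V1_F0090,V1,73.204,78.852,gadoid
V1_F0091,V1,176.335,177.243,gadoid
V1_F0092,V1,237.576,238.565,gadoid
V1_F0093,V1,197.723,198.124,gadoid
V1_F0094,V1,194.087,195.883,gadoid
V1_F0095,V1,129.606,130.413,gadoid
V1_F0096,V1,20.028,20.463,gadoid
V1_F0097,V1,28.385,30.637,gadoid
V1_F0098,V1,70.77,71.084,gadoid
V1_F0099,V1,158.926,161.182,gadoid
V1_F0100,V1,268.927,269.962,gadoid
V1_F0101,V1,170.585,174.783,gadoid
V1_F0102,V1,159.48,160.46,gadoid
V2_F0000,V2,85.74,88.505,gadoid
V2_F0001,V2,135.138,137.004,gadoid
V2_F0002,V2,71.348,78.658,gadoid
V2_F0003,V2,238.004,241.529,gadoid
V2_F0004,V2,21.889,22.483,gadoid
V2_F0005,V2,209.671,213.689,gadoid
V2_F0006,V2,41.683,42.603,gadoid
V2_F0007,V2,195.278,196.013,gadoid
V2_F0008,V2,197.992,203.709,gadoid
V2_F0009,V2,30.753,35.792,gadoid
V2_F0010,V2,75.28,76.025,gadoid
V2_F0011,V2,226.786,231.499,gadoid
V2_F0012,V2,216.594,219.498,gadoid
V2_F0013,V2,132.1,134.661,gadoid
V2_F0014,V2,155.565,156.29,gadoid
V2_F0015,V2,139.529,141.237,gadoid
V2_F0016,V2,13.785,14.435,gadoid
V2_F0017,V2,133.041,134.441,gadoid
V2_F0018,V2,78.351,79.316,gadoid
V2_F0019,V2,275.33,276.35,gadoid
V2_F0020,V2,238.98,239.512,gadoid
V2_F0021,V2,239.329,239.839,gadoid
V2_F0022,V2,41.025,41.79,gadoid
V2_F0023,V2,42.001,42.664,gadoid
V2_F0024,V2,244.669,245.981,gadoid
V2_F0025,V2,4.802,9.126,gadoid
V2_F0026,V2,215.435,216.38,gadoid
V2_F0027,V2,101.651,102.48,gadoid
V2_F0028,V2,265.073,266.416,gadoid
V2_F0029,V2,39.27,40.29,gadoid
V2_F0030,V2,74.253,75.8,gadoid
V2_F0031,V2,216.916,219.491,gadoid
V2_F0032,V2,295.846,299.073,gadoid
V2_F0033,V2,78.53,80.09,gadoid
V2_F0034,V2,97.346,98.087,gadoid
V2_F0035,V2,52.479,57.836,gadoid
V2_F0036,V2,78.135,83.087,gadoid
V2_F0037,V2,252.463,253.151,gadoid
V2_F0038,V2,234.912,240.862,gadoid
V2_F0039,V2,107.828,108.126,gadoid
V2_F0040,V2,2.289,3.823,gadoid
V2_F0041,V2,31.018,33.234,gadoid
V2_F0042,V2,271.023,274.97,gadoid
V2_F0043,V2,291.123,294.584,gadoid
V2_F0044,V2,268.537,269.319,gadoid
V2_F0045,V2,210.351,210.896,gadoid
V2_F0046,V2,290.966,293.205,gadoid
V2_F0047,V2,196.269,199.945,gadoid
V2_F0048,V2,266.574,268.516,gadoid
V2_F0049,V2,213.901,220.227,gadoid
V2_F0050,V2,44.275,50.379,gadoid
V2_F0051,V2,211.715,212.184,gadoid
V2_F0052,V2,250.55,251.323,gadoid
V2_F0053,V2,112.721,114.379,gadoid
V2_F0054,V2,123.85,125.95,gadoid
V2_F0055,V2,28.972,29.253,gadoid
V2_F0056,V2,117.662,118.229,gadoid
V2_F0057,V2,99.774,100.026,gadoid
V2_F0058,V2,189.142,191.708,gadoid
V2_F0059,V2,281.004,282.999,gadoid
V2_F0060,V2,59.35,59.663,gadoid
V2_F0061,V2,164.293,164.971,gadoid
V2_F0062,V2,185.667,185.957,gadoid
V2_F0063,V2,243.42,243.526,gadoid
V2_F0064,V2,206.783,213.804,gadoid
V2_F0065,V2,68.48,70.96,gadoid
V2_F0066,V2,279.438,280.396,gadoid
V2_F0067,V2,126.432,127.877,gadoid
V2_F0068,V2,161.114,163.687,gadoid
V2_F0069,V2,128.24,131.008,gadoid
V2_F0070,V2,37.706,38.422,gadoid
V2_F0071,V2,125.004,125.895,gadoid
V2_F0072,V2,175.713,177.052,gadoid
V2_F0073,V2,41.028,43.528,gadoid
V2_F0074,V2,22.42,23.72,gadoid
V2_F0075,V2,39.536,42.38,gadoid
V2_F0076,V2,190.214,201.04,gadoid
V2_F0077,V2,18.734,22.293,gadoid
V2_F0078,V2,113.403,113.679,gadoid
V2_F0079,V2,160.499,163.001,gadoid
V2_F0080,V2,90.484,91.571,gadoid
V2_F0081,V2,205.748,206.823,gadoid
V2_F0082,V2,23.593,25.008,gadoid
V2_F0083,V2,287.826,290.913,gadoid
V2_F0084,V2,98.166,99.134,gadoid
V2_F0085,V2,197.641,199.5,gadoid
V2_F0086,V2,87.656,87.948,gadoid
V2_F0087,V2,214.813,215.371,gadoid
V2_F0088,V2,111.667,112.64,gadoid
V2_F0089,V2,188.701,190.864,gadoid
V2_F0090,V2,70.208,70.739,gadoid
V2_F0091,V2,280.98,282.631,gadoid
V2_F0092,V2,142.361,143.94,gadoid
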