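fish_id,video_id,rank,time,vertical,horizontal,success
V1_F0001,V1,1,184.784,top,center,False
V1_F0002,V1,1,160.294,top,left,False
V1_F0002,V1,2,161.095,top,center,False
V1_F0003,V1,1,61.079,bottom,left,False
V1_F0003,V1,2,62.161,center,left,False
V1_F0003,V1,3,66.975,center,left,False
V1_F0005,V1,1,27.775,center,center,False
V1_F0005,V1,2,31.165,top,center,False
V1_F0008,V1,1,265.055,top,left,False
V1_F0008,V1,2,266.702,center,right,False
V1_F0009,V1,1,15.966,top,right,False
V1_F0009,V1,2,17.067,center,center,False
V1_F0012,V1,1,218.724,center,left,False
V1_F0014,V1,1,83.459,top,center,False
V1_F0014,V1,2,84.318,top,center,True
V1_F0015,V1,1,131.92,top,left,False
V1_F0015,V1,2,134.294,top,right,False
V1_F0015,V1,3,134.532,top,center,False
V1_F0017,V1,1,2.914,top,left,False
V1_F0017,V1,2,7.111,top,center,True
V1_F0019,V1,1,247.12,center,center,False
V1_F0019,V1,2,248.573,center,left,False
V1_F0019,V1,3,249.435,top,right,False
V1_F0021,V1,1,287.984,bottom,right,False
V1_F0022,V1,1,52.037,top,right,True
V1_F0023,V1,1,278.556,center,center,False
V1_F0023,V1,2,280.808,top,center,False
V1_F0026,V1,1,6.239,top,left,False
V1_F0026,V1,2,10.831,top,right,False
V1_F0026,V1,3,10.902,top,center,True
V1_F0032,V1,1,151.952,top,center,False
V1_F0034,V1,1,83.965,bottom,left,False
V1_F0035,V1,1,277.576,bottom,center,True
V1_F0036,V1,1,39.754,top,left,False
V1_F0036,V1,2,40.142,center,center,False
V1_F0037,V1,1,200.844,top,left,False
V1_F0038,V1,1,202.265,top,center,False
V1_F0038,V1,2,203.781,center,left,False
V1_F0038,V1,3,204.518,top,center,False
V1_F0038,V1,4,205.114,center,right,False
V1_F0041,V1,1,162.922,bottom,left,False
V1_F0042,V1,1,146.848,top,center,False
V1_F0046,V1,1,229.998,center,right,False
V1_F0046,V1,2,230.45,top,left,False
V1_F0046,V1,3,231.221,bottom,right,True
V1_F0048,V1,1,131.673,center,center,True
V1_F0049,V1,1,210.767,top,left,False
V1_F0050,V1,1,209.242,top,left,False
V1_F0051,V1,1,245.295,top,right,False
V1_F0052,V1,1,252.893,top,right,False
V1_F0053,V1,1,206.075,top,right,False
V1_F0054,V1,1,299.515,bottom,left,False
V1_F0056,V1,1,78.589,top,center,False
V1_F0057,V1,1,5.954,bottom,right,False
V1_F0057,V1,2,6.156,top,center,False
V1_F0057,V1,3,12.42,center,right,False
V1_F0059,V1,1,70.959,top,center,False
V1_F0060,V1,1,290.155,top,left,False
V1_F0061,V1,1,38.252,top,right,False
V1_F0062,V1,1,84.322,top,center,False
V1_F0062,V1,2,84.507,center,left,False
V1_F0062,V1,3,85.246,top,right,True
V1_F0063,V1,1,159.636,center,center,False
V1_F0065,V1,1,299.915,top,left,False
V1_F0068,V1,1,213.053,top,center,False
V1_F0070,V1,1,250.277,center,left,False
V1_F0071,V1,1,7.628,top,center,False
V1_F0074,V1,1,234.234,top,left,False
V1_F0074,V1,2,236.849,top,right,False
V1_F0075,V1,1,190.379,center,left,True
V1_F0077,V1,1,222.637,top,center,False
V1_F0077,V1,2,223.324,top,center,False
V1_F0077,V1,3,223.913,top,right,False
V1_F0078,V1,1,93.012,top,center,True
V1_F0081,V1,1,79.622,top,center,False
V1_F0081,V1,2,80.08,bottom,left,True
V1_F0082,V1,1,236.41,top,center,False
V1_F0083,V1,1,213.564,top,right,False
V1_F0084,V1,1,265.855,top,left,False
V1_F0084,V1,2,267.819,top,left,False
V1_F0088,V1,1,193.969,top,right,False
V1_F0091,V1,1,176.937,bottom,center,False
V1_F0093,V1,1,197.77,top,center,False
V1_F0094,V1,1,195.883,top,center,True
V1_F0095,V1,1,130.16,bottom,right,False
V1_F0096,V1,1,20.343,top,center,False
V1_F0097,V1,1,28.448,top,center,False
V1_F0098,V1,1,71.055,top,center,False
V1_F0099,V1,1,159.244,top,right,False
V1_F0101,V1,1,171.733,top,right,False
V2_F0000,V2,1,86.823,top,left,False
V2_F0002,V2,1,73.916,top,center,False
V2_F0003,V2,1,238.779,center,center,False
V2_F0003,V2,2,240.886,top,left,False
V2_F0003,V2,3,241.164,top,left,False
V2_F0005,V2,1,210.298,top,right,False
V2_F0005,V2,2,211.254,bottom,right,False
V2_F0005,V2,3,211.747,bottom,left,False
V2_F0008,V2,1,198.852,top,center,False
V2_F0008,V2,2,199.002,top,left,False
V2_F0008,V2,3,200.789,top,center,False
V2_F0008,V2,4,202.221,top,center,False
V2_F0009,V2,1,30.957,top,left,False
V2_F0009,V2,2,33.978,center,left,False
V2_F0009,V2,3,34.949,top,left,False
V2_F0010,V2,1,75.613,center,right,False
V2_F0010,V2,2,76.025,top,center,True
V2_F0011,V2,1,230.208,top,right,False
V2_F0011,V2,2,231.499,top,left,True
V2_F0012,V2,1,216.798,top,right,False
V2_F0013,V2,1,132.156,center,center,False
V2_F0014,V2,1,156.29,top,right,True
V2_F0016,V2,1,13.986,top,center,False
V2_F0017,V2,1,133.96,top,left,False
V2_F0028,V2,1,265.828,top,center,False
V2_F0029,V2,1,39.437,top,center,False
V2_F0029,V2,2,39.802,top,center,False
V2_F0030,V2,1,74.931,bottom,left,False
V2_F0031,V2,1,216.94,top,right,False
V2_F0031,V2,2,218.642,top,left,False
V2_F0031,V2,3,219.06,top,right,False
V2_F0032,V2,1,297.017,center,center,False
V2_F0032,V2,2,297.13,top,left,False
V2_F0032,V2,3,297.373,center,center,False
V2_F0032,V2,4,298.996,top,center,False
V2_F0035,V2,1,52.86,top,left,False
V2_F0035,V2,2,53.002,top,left,False
V2_F0035,V2,3,54.484,top,right,False
V2_F0039,V2,1,108.126,top,center,True
V2_F0040,V2,1,3.35,top,left,False
V2_F0041,V2,1,31.916,center,center,False
V2_F0042,V2,1,274.108,top,center,False
V2_F0043,V2,1,291.876,center,left,False
V2_F0043,V2,2,294.516,bottom,right,False
V2_F0043,V2,3,294.584,top,center,True
V2_F0044,V2,1,268.704,top,left,False
V2_F0045,V2,1,210.418,top,center,False
V2_F0046,V2,1,291.618,top,right,False
V2_F0047,V2,1,196.926,center,right,False
V2_F0048,V2,1,268.516,bottom,right,True
V2_F0049,V2,1,214.442,center,left,False
V2_F0049,V2,2,220.227,center,center,True
V2_F0050,V2,1,48.56,top,center,False
V2_F0055,V2,1,29.253,top,left,True
V2_F0059,V2,1,281.618,bottom,right,False
V2_F0062,V2,1,185.732,top,left,False
V2_F0063,V2,1,243.526,top,left,True
V2_F0064,V2,1,206.948,bottom,left,False
V2_F0064,V2,2,212.033,top,left,False
V2_F0064,V2,3,213.804,bottom,right,True
V2_F0068,V2,1,161.498,top,center,False
V2_F0070,V2,1,38.404,top,left,False
V2_F0074,V2,1,23.364,top,left,False
V2_F0075,V2,1,40.554,top,left,False
V2_F0075,V2,2,40.773,top,center,False
V2_F0076,V2,1,190.287,top,right,False
V2_F0076,V2,2,191.794,center,center,False
V2_F0076,V2,3,193.489,top,right,False
V2_F0076,V2,4,193.874,top,center,False
V2_F0076,V2,5,197.449,top,right,False
V2_F0076,V2,6,197.698,center,center,False
V2_F0076,V2,7,200.616,bottom,right,False
V2_F0080,V2,1,91.29,top,left,False
V2_F0082,V2,1,23.66,center,right,False
V2_F0082,V2,2,24.909,top,left,False
V2_F0084,V2,1,98.821,top,center,False
V2_F0085,V2,1,199.193,top,center,False
V2_F0089,V2,1,189.587,top,right,False
V2_F0092,V2,1,142.971,top,left,False
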