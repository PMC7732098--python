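# escapement

Survival analysis of fish escapement behavior in trawls from video
ethograms.

## The problem

Underwater cameras mounted in the extension of a bottom trawl record fish
interacting with selective devices (square-mesh panels and cylinders).
Each fish is only visible for a short, variable window — a couple of
seconds on average — before it drifts out of frame, so naive percentages
of "fish that attempted to escape" are biased: a fish that left the frame
without attempting might well have attempted later.  This package treats
escapement attempts as a right-censored recurrent-event process and gives
gear-technology researchers the estimators that make such footage
quantitatively comparable:

* **How likely is a fish to attempt an escape, and at what rate?**
  A Weibull mixture ("cure") survival model.
* **Does the rate change with repeated attempts, or over the tow?**
  AIC selection over a 32-model grid of covariate placements.
* **How likely is an attempt to succeed?** Binomial (logit) regression
  with AIC selection.
* **Do attempts arrive as expected from independent fish?** Cumulative
  attempt curves against Monte-Carlo homogeneous-Poisson envelopes.

## The model

The time `T` from a fish's arrival in frame (or from its previous
attempt) to its next escapement attempt follows

```
S(t) = P(T > t) = 1 - π + π · exp(-(αt)^γ)
```

where `α > 0` (1/s) and `γ > 0` are Weibull scale and shape and
`π ∈ (0, 1]` is the fraction of the population that would ever attempt:
the survival curve flattens onto the asymptote `1 - π` instead of
reaching zero.  With `γ = 1` the process is exponential (memoryless, mean
gap `1/α`).  Fish that leave the frame contribute right-censored terms
`S(T)`; observed attempts contribute the density `f(T) = -dS/dt`.  Attempt
rank (first / second / third-and-later gap) and video sequence enter as
categorical covariates on any subset of `(α, γ, π)`, additively on the
link scale (log, log, logit); enumerating the placements with and without
the `γ = 1` restriction yields 32 candidate models ranked by AIC.

A synthetic-ethogram generator (`escapement.synth`) simulates this whole
observation process — Poisson or pulsed arrivals, lognormal observation
windows, per-gap cure draws, per-rank Weibull gaps, Bernoulli success —
so every estimator can be validated against known truth.

## Worked example

The package ships a small deterministic reference ethogram (~200 fish
over two 300-s videos, regenerable bit-identically from its seed):

```python
import escapement as esc

obs, states, attempts = esc.read_event_log(esc.fixture_path())
data = esc.build_survival_data(obs, attempts)   # 343 gap rows, 169 events
fits = esc.fit_grid(data, seed=0)               # 32 models, ranked by AIC
best = fits[0]
print(best.spec.describe(), round(best.aic, 2))
print(best.estimates.table().drop_duplicates("rank_group"))
```

prints

```
M8: rank->(alpha+gamma=1) video->(-) [gamma=1] 639.47
rank_group    alpha  gamma       pi
        R1 0.590734    1.0 0.919963
        R2 0.295949    1.0 0.919963
    R3plus 0.469848    1.0 0.919963
```

AIC selects M8: attempt gaps are exponential (`γ = 1`, a constant
instantaneous attempt rate), the rate differs by attempt rank — here
0.59/s before the first attempt, 0.30/s before the second (the fitted
mean wait `1/α` lengthens after a failed attempt) — and an estimated 92%
of this simulated population would eventually attempt (the generator's
truth is `α = (0.6, 0.29, 0.38)`, `π = 0.88`).  The attempt-success side:

```python
ds = esc.build_success_dataset(attempts)
print(esc.fit_logistic(ds).fitted[0])      # 0.130 — null success probability
print(esc.position_chi_square(attempts, "horizontal"))
                                           # (3.99, 2, 0.14) — no horizontal bias
```

The same pipeline is available from the shell:

```sh
escapement simulate --seed 1 --out run1
escapement attempts-grid run1 --out run1   # 32-row AIC table + selection JSON
escapement success run1 --out run1
escapement dynamics run1 --out run1
```

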