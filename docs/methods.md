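# Methods

## The escapement process and its observation model

A fish entering the camera's field of view is followed until it leaves
(its *observation window*).  During that window it may make escapement
attempts: voluntary swims toward the netting with snout contact, each of
which succeeds (the fish passes a mesh and is gone) or fails.  The clock
of interest restarts at every attempt, giving a sequence of *gap times*
per fish: entry → first attempt (rank 1), first → second attempt (rank
2), and so on.  A fish that leaves without a further attempt contributes
a right-censored gap from its last reset to its exit.  Gaps are modelled
as independent draws from a Weibull mixture

    S(t) = 1 - π + π exp(-(αt)^γ),

so each gap either belongs to the attempting fraction π (Weibull with
scale α in 1/s and shape γ) or, with probability 1 − π, never ends in an
attempt.  Within-fish dependence beyond the rank covariate is not
modelled; model selection over rank effects is the mechanism by which
systematic changes across successive gaps are detected.

Censoring is assumed non-informative: a fish's window length carries no
information about its attempt propensity.  The generator has an
`informative_censoring` toggle (off by default) to study violations.

## Likelihood, links and optimization

Events contribute `log f(T)`, censored rows `log S(T)`, with
`f(t) = π γ α^γ t^(γ-1) exp(-(αt)^γ)`.  Parameters are estimated on an
unconstrained link scale — `log α`, `log γ`, `logit π` — by L-BFGS-B
(quasi-Newton) with numerical gradients.  Numerical choices:

* **Zero gaps.**  Annotated attempt times can coincide with entry; event
  gaps are clamped below at ε = 0.02 s (half a PAL frame) before
  likelihood evaluation so the density stays finite for γ ≠ 1.
  Configurable per fit.
* **Boundary π = 1.**  The logit predictor is clipped at ±20, allowing
  π to saturate at 1 − 2·10⁻⁹ (no cure fraction) without the optimizer
  running to infinity.  `log γ` is clipped at ±5, `log α` at ±30.
* **Starting values.**  The first start is a method-of-moments guess
  (α₀ = events / total gap time, π₀ = fraction of fish with ≥1 event,
  γ₀ = 1); further starts add seeded N(0, 0.5²) noise on the link scale.
  Single-model fits default to 10 starts; grid fits to 3, because the
  moment start is reliable on these smooth likelihoods and the grid
  multiplies every start by 32.
* **Convergence.**  Objective tolerance 1e-8; ties between restarts
  resolved toward the lower negative log-likelihood.
* **Degenerate designs.**  A covariate level with no events leaves its
  parameters weakly identified; the fit proceeds but is flagged.

## Covariate structure and the 32-model grid

Attempt rank is pooled to three levels (R1, R2, R3plus — ranks of three
and beyond share a level) and video sequence has two (V1, V2).  Either
covariate may act on any subset of (α, γ, π); with both active the same
subset applies to each, with additive main effects on the link scale and
no interaction (the parsimonious GLM convention; an interaction model is
not identified at these sample sizes).  Together with the exponential
restriction γ = 1 this yields 32 structures, M0–M31: seven free-γ and
three γ=1 rank-only placements, the two null models, the same ten for
video, and the same ten on both covariates.  Free-parameter counts add
one per baseline (γ = 1 contributes none), two per rank placement and one
per video placement; models are ranked by AIC = 2k − 2 logL with ties
broken by fewer parameters.

Kaplan–Meier curves of the same gap data (pooled or per covariate group)
provide the nonparametric reference; the product-limit computation is
delegated to lifelines.

## Attempt success

Success of each attempt is Bernoulli; candidate predictors are rank
group, video and one opaque user-supplied binary attempt-level covariate
(the analysis framework reserves a third slot without interpreting it).
The logit fit is by iteratively reweighted least squares with deviance
tolerance 1e-8; unused factor levels are dropped from the design, and
under complete separation coefficients are capped at ±15 on the logit
scale and flagged.  All additive subsets (8 models, or 4 without the
extra covariate) are ranked by AIC.  The intercept-only model's fitted
probability equals the sample success proportion exactly, which the test
suite asserts; coefficients are cross-checked against statsmodels GLM.

## Temporal dynamics

If individual attempt rates are constant and arrivals homogeneous
Poisson, the population's cumulative attempt count grows linearly.  The
package fits ordinary least squares to the cumulative step curve over an
initial window (default 30 s, with a 15 s alternate) — by default at the
event times themselves, since that is how the step curve is drawn; a
regular-grid variant is available by flag because the construction is
ambiguous in general.  Departures from homogeneity are diagnosed against
a Monte-Carlo pointwise 95% envelope of simulated homogeneous-Poisson
cumulative paths on a 1-s grid (Monte Carlo rather than a normal
approximation because per-second counts are small); the reported statistic
is the fraction of grid points at which the observed curve leaves the
band.  A same-process path exceeds a 95% pointwise band at roughly 5% of
points; pulses of near-simultaneous attempts push the fraction far
higher.  No formal point-process inference is attempted.

## The chi-square position test

Attempt positions on an axis (vertical or horizontal) are tested against
a uniform distribution over that axis's three categories with a Pearson
goodness-of-fit statistic, df = categories − 1.  This is an
interpretation: a uniform null asks "is the axis used evenly?", which is
the natural reading for a single-axis test; it is not a contingency test
between axes.

## The synthetic generator

`simulate_ethogram` emulates the observation process end to end: fish
arrive homogeneously (default 1/3 fish/s per 300-s video, two videos,
hence ~200 fish) or in configurable pulses; each fish draws a lognormal
observation window (mean 2.23 s, sd 2.5 s, truncated to [0.25, 25] s);
before every gap the fish stops attempting for good with probability
1 − π (so each gap's survival curve asymptotes at 1 − π, exactly the
mixture assumption, and the ever-attempting fraction under unlimited
observation is π); gaps are Weibull with the rank-specific scale (ranks
past three keep the R3plus scale); attempts beyond the window are
discarded — which *is* the right-censoring mechanism, not an
approximation of it; each attempt succeeds with probability 0.148 and
success ends the window at that instant.  Default parameters are the
study conditions: π = 0.88, γ = 1, α = (0.6, 0.29, 0.38) 1/s.  Attempt
positions are drawn top-biased (0.69, 0.21, 0.10) vertically and uniform
horizontally.

Behavioral-state intervals (speed/orientation/vertical/horizontal) come
from a simple per-axis Markov switcher (exponential dwell, 0.5
switches/s, starting weights loosely shaped like observed budgets).  The
switcher exists to exercise time-budget code; it does not model swimming
dynamics, correlations between axes, or position-dependent attempt
behavior, so passing time-budget tests says nothing about real swimming
structure.  Likewise the generator draws windows independently of
attempt propensity; real footage may violate that (e.g. attempting fish
hold station longer), which is why the informative-censoring toggle
exists for robustness experiments.

Every fish owns a random sub-stream keyed by (seed, video, fish index):
enlarging the population or adding pulses never perturbs previously
generated fish.  All emitted times are rounded to 1 ms, far below the
~40 ms video frame.  The shipped reference fixture is the default
configuration at seed 20201211 (196 fish, 169 attempts) and regenerates
bit-identically.

## Problem sizes used in validation

The test suite and acceptance script validate estimator behavior at two
scales chosen as representative: the study scale (~200 fish, where
estimates are recognizably noisy) and an estimation-friendly scale of
~1220 fish yielding ~2000 gap rows, at which 20 replicated simulations
give median relative errors below 10% for the rank-specific rates and
the attempting fraction, and AIC selects a rank-on-α exponential
structure in ≥70% of replicates.  "Selects the structure" counts any
winning model with α on rank and γ fixed at 1: AIC is expected to admit
a one-extra-parameter neighbor of the truth in a nontrivial fraction of
replicates, and that is a property of AIC, not a recovery failure.
Envelope calibration uses 1000 simulated paths.

## Known limitations

* Gaps within a fish are treated as independent given rank; frailty or
  learning effects beyond rank shifts are out of scope.
* Interval censoring (attempts between frames) is ignored; times are
  taken as exact.
* The two-covariate models are additive by construction; a rank × video
  interaction cannot be detected.
* The Poisson envelope is a pointwise band, so its exceedance fraction
  is a diagnostic, not a formal global test.
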