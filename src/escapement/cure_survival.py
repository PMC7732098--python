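"""Weibull mixture ("cure") survival model for recurrent escapement attempts.

The model: a fraction ``pi`` of the population will eventually attempt to
escape, with gap times following a Weibull law with scale ``alpha`` (1/s)
and shape ``gamma``; the remaining ``1 - pi`` never attempt.  The survival
function of the time to the next attempt is

    S(t) = 1 - pi + pi * exp(-(alpha * t)^gamma)

so the attempt rate decays toward an asymptote of ``1 - pi``.  With
``gamma = 1`` this reduces to an exponential (memoryless) process with mean
gap ``1/alpha``.  Fish that leave the field of view without attempting are
right-censored and contribute ``S(T)`` to the likelihood; observed attempts
contribute the density ``f(T) = -dS/dt``.

Covariates -- the rank of the attempt (first / second / third-and-later) and
the video sequence (beginning vs middle of the tow) -- may act on any subset
of (alpha, gamma, pi), additively on the link scale (log for alpha and
gamma, logit for pi).  Enumerating the covariate placements, with and
without the exponential restriction ``gamma = 1``, yields a grid of 32
candidate models compared by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.optimize import minimize
from scipy.special import expit, logit

PARAM_NAMES = ("alpha", "gamma", "pi")
RANK_LEVELS = ("R1", "R2", "R3plus")
VIDEO_LEVELS = ("V1", "V2")

#: Event gap times are clamped below at this value (seconds) before
#: likelihood evaluation.  Annotated attempt times can coincide with the
#: fish's entry (a zero gap), where the Weibull density is degenerate for
#: gamma != 1; half a PAL video frame is the finest resolvable gap.
DEFAULT_EPSILON = 0.02

#: Saturation guard on the logit scale: pi may approach 1 (no cure
#: fraction) but the linear predictor is clipped to +/- this value.
LOGIT_GUARD = 20.0

_LINK = {"alpha": np.log, "gamma": np.log, "pi": logit}


# ---------------------------------------------------------------------------
# Model specification and the 32-model grid

@dataclass(frozen=True)
class ModelSpec:
    """Which covariates act on which parameters.

    ``rank_on`` / ``video_on`` are the subsets of ("alpha", "gamma", "pi")
    on which attempt rank / video sequence act; ``gamma_fixed_one``
    restricts the Weibull to its exponential special case (in which case
    gamma carries no covariates and no free parameter).
    """

    id: str
    rank_on: frozenset = frozenset()
    video_on: frozenset = frozenset()
    gamma_fixed_one: bool = False

    def __post_init__(self):
        for s in (self.rank_on, self.video_on):
            if not s <= set(PARAM_NAMES):
                raise ValueError(f"unknown parameter in covariate set {set(s)}")
        if self.gamma_fixed_one and "gamma" in (self.rank_on | self.video_on):
            raise ValueError(
                f"{self.id}: gamma fixed at 1 cannot carry covariates")

    def describe(self) -> str:
        def fmt(s):
            parts = [p for p in PARAM_NAMES if p in s]
            if self.gamma_fixed_one and "alpha" in parts:
                parts.insert(1, "gamma=1")
            return "+".join(parts) if parts else "-"
        return (f"{self.id}: rank->({fmt(self.rank_on)}) "
                f"video->({fmt(self.video_on)})"
                + (" [gamma=1]" if self.gamma_fixed_one else ""))


_FREE_SUBSETS = [("alpha", "gamma", "pi"), ("alpha", "gamma"),
                 ("alpha", "pi"), ("gamma", "pi"),
                 ("alpha",), ("gamma",), ("pi",)]
_G1_SUBSETS = [("alpha", "pi"), ("alpha",), ("pi",)]


def enumerate_grid() -> list[ModelSpec]:
    """The full 32-model grid over covariate placements.

    M0-M9 place rank on the seven free-gamma subsets then the three
    exponential (gamma = 1) subsets; M10/M11 are the covariate-free null
    models (free gamma, gamma = 1); M12-M21 repeat the ten covariate
    placements for video; M22-M31 place the same subset on both covariates
    simultaneously (additive main effects).
    """
    specs: list[ModelSpec] = []
    i = 0
    for s in _FREE_SUBSETS:
        specs.append(ModelSpec(f"M{i}", rank_on=frozenset(s))); i += 1
    for s in _G1_SUBSETS:
        specs.append(ModelSpec(f"M{i}", rank_on=frozenset(s),
                               gamma_fixed_one=True)); i += 1
    specs.append(ModelSpec("M10"))
    specs.append(ModelSpec("M11", gamma_fixed_one=True))
    i = 12
    for s in _FREE_SUBSETS:
        specs.append(ModelSpec(f"M{i}", video_on=frozenset(s))); i += 1
    for s in _G1_SUBSETS:
        specs.append(ModelSpec(f"M{i}", video_on=frozenset(s),
                               gamma_fixed_one=True)); i += 1
    for s in _FREE_SUBSETS:
        specs.append(ModelSpec(f"M{i}", rank_on=frozenset(s),
                               video_on=frozenset(s))); i += 1
    for s in _G1_SUBSETS:
        specs.append(ModelSpec(f"M{i}", rank_on=frozenset(s),
                               video_on=frozenset(s),
                               gamma_fixed_one=True)); i += 1
    assert len(specs) == 32
    return specs


def spec_by_id(model_id: str) -> ModelSpec:
    for s in enumerate_grid():
        if s.id == model_id:
            return s
    raise KeyError(f"unknown model id {model_id!r} (expected M0..M31)")


# ---------------------------------------------------------------------------
# Parameters

@dataclass
class ParameterSet:
    """Link-scale coefficients for each model parameter.

    ``coefficients[param]`` maps coefficient names (``baseline``, ``R2``,
    ``R3plus``, ``V2``) to values on the link scale (log for alpha and
    gamma, logit for pi).  A gamma fixed at 1 is stored as an empty dict.
    """

    coefficients: dict = field(default_factory=dict)

    @classmethod
    def from_values(cls, alpha, gamma, pi, *, gamma_fixed_one=False):
        """Build a covariate-free set from natural-scale values; ``alpha``
        may be a mapping rank level -> value to put a rank effect on alpha."""
        coefs: dict = {}
        if isinstance(alpha, dict):
            base = np.log(alpha["R1"])
            coefs["alpha"] = {"baseline": base}
            for lvl in ("R2", "R3plus"):
                if lvl in alpha:
                    coefs["alpha"][lvl] = np.log(alpha[lvl]) - base
        else:
            coefs["alpha"] = {"baseline": np.log(alpha)}
        coefs["gamma"] = {} if gamma_fixed_one else {"baseline": np.log(gamma)}
        coefs["pi"] = {"baseline": float(np.clip(logit(pi), -LOGIT_GUARD,
                                                 LOGIT_GUARD))}
        return cls(coefs)

    def effective(self, rank_group: str = "R1", video: str = "V1"):
        """Resolve the natural-scale (alpha, gamma, pi) for one covariate
        combination."""
        out = []
        for p in PARAM_NAMES:
            c = self.coefficients.get(p, {})
            if p == "gamma" and not c:
                out.append(1.0)
                continue
            eta = c.get("baseline", 0.0)
            if rank_group == "R2":
                eta += c.get("R2", 0.0)
            elif rank_group == "R3plus":
                eta += c.get("R3plus", 0.0)
            if video == "V2":
                eta += c.get("V2", 0.0)
            if p == "pi":
                out.append(float(expit(np.clip(eta, -LOGIT_GUARD, LOGIT_GUARD))))
            else:
                out.append(float(np.exp(eta)))
        return tuple(out)

    def table(self) -> pd.DataFrame:
        """Natural-scale (alpha, gamma, pi) for every covariate combination."""
        rows = [(r, v, *self.effective(r, v))
                for r in RANK_LEVELS for v in VIDEO_LEVELS]
        return pd.DataFrame(
            rows, columns=["rank_group", "video", "alpha", "gamma", "pi"])


# ---------------------------------------------------------------------------
# Survival / density / likelihood

def survival_function(t, alpha, gamma, pi):
    """S(t) = 1 - pi + pi * exp(-(alpha t)^gamma), the probability that no
    attempt has occurred by t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    _check_params(alpha, gamma, pi)
    out = 1.0 - pi + pi * np.exp(-np.power(alpha * t, gamma))
    return out if out.ndim else float(out)


def density_function(t, alpha, gamma, pi):
    """f(t) = pi * gamma * alpha^gamma * t^(gamma-1) * exp(-(alpha t)^gamma);
    the sub-density of attempt times, integrating to pi."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    _check_params(alpha, gamma, pi)
    out = (pi * gamma * alpha ** gamma * np.power(t, gamma - 1.0)
           * np.exp(-np.power(alpha * t, gamma)))
    return out if out.ndim else float(out)


def _check_params(alpha, gamma, pi):
    if not (np.all(np.asarray(alpha) > 0) and np.all(np.asarray(gamma) > 0)):
        raise ValueError("alpha and gamma must be > 0")
    pi = np.asarray(pi)
    if not (np.all(pi >= 0) and np.all(pi <= 1)):
        raise ValueError("pi must lie in [0, 1]")


def _designs(data: pd.DataFrame, spec: ModelSpec):
    """Design matrix and coefficient names per parameter (None for a gamma
    fixed at 1)."""
    n = len(data)
    r2 = (data["rank_group"] == "R2").to_numpy(float)
    r3 = (data["rank_group"] == "R3plus").to_numpy(float)
    v2 = (data["video"] == "V2").to_numpy(float)
    out = {}
    for p in PARAM_NAMES:
        if p == "gamma" and spec.gamma_fixed_one:
            out[p] = None
            continue
        cols, names = [np.ones(n)], ["baseline"]
        if p in spec.rank_on:
            cols += [r2, r3]
            names += ["R2", "R3plus"]
        if p in spec.video_on:
            cols.append(v2)
            names.append("V2")
        out[p] = (np.column_stack(cols), names)
    return out


def _unpack(theta, designs):
    i, etas = 0, {}
    for p in PARAM_NAMES:
        d = designs[p]
        if d is None:
            etas[p] = None
            continue
        X, names = d
        k = len(names)
        etas[p] = X @ theta[i:i + k]
        i += k
    return etas


def _theta_to_params(theta, designs) -> ParameterSet:
    coefs, i = {}, 0
    for p in PARAM_NAMES:
        d = designs[p]
        if d is None:
            coefs[p] = {}
            continue
        _, names = d
        coefs[p] = {nm: float(theta[i + j]) for j, nm in enumerate(names)}
        i += len(names)
    return ParameterSet(coefs)


def _params_to_theta(params: ParameterSet, designs) -> np.ndarray:
    theta = []
    for p in PARAM_NAMES:
        d = designs[p]
        if d is None:
            continue
        _, names = d
        c = params.coefficients.get(p, {})
        theta.extend(c.get(nm, 0.0) for nm in names)
    return np.asarray(theta, dtype=float)


def _negloglik_factory(data: pd.DataFrame, spec: ModelSpec, epsilon: float):
    designs = _designs(data, spec)
    t_raw = data["gap_time"].to_numpy(float)
    event = data["event"].to_numpy(bool)
    # zero event gaps carry no information about gamma and blow up the
    # density; clamp to the resolution floor
    t = np.where(event, np.maximum(t_raw, epsilon), t_raw)
    log_t = np.log(np.where(t > 0, t, 1.0))
    positive = t > 0

    def nll(theta):
        etas = _unpack(theta, designs)
        log_alpha = np.clip(etas["alpha"], -30.0, 30.0)
        if etas["gamma"] is None:
            gamma = 1.0
            log_gamma = 0.0
        else:
            log_gamma = np.clip(etas["gamma"], -5.0, 5.0)
            gamma = np.exp(log_gamma)
        pi = expit(np.clip(etas["pi"], -LOGIT_GUARD, LOGIT_GUARD))
        # (alpha t)^gamma, with t = 0 handled exactly
        z = np.where(positive,
                     np.exp(np.clip(gamma * (log_alpha + log_t), -700, 700)),
                     0.0)
        ll_event = (np.log(pi) + log_gamma + gamma * log_alpha
                    + (gamma - 1.0) * log_t - z)
        surv = 1.0 - pi + pi * np.exp(-z)
        ll_cens = np.log(np.maximum(surv, 1e-300))
        total = np.sum(np.where(event, ll_event, ll_cens))
        return np.inf if not np.isfinite(total) else -total

    return nll, designs


def log_likelihood(data: pd.DataFrame, spec: ModelSpec, params: ParameterSet,
                   epsilon: float = DEFAULT_EPSILON) -> float:
    """Right-censored mixture log-likelihood: events contribute log f(T),
    censored rows log S(T), with (alpha, gamma, pi) resolved per row from
    the covariates the spec activates.  Returns -inf when the likelihood is
    degenerate (e.g. an observed event under pi = 0)."""
    if data.empty:
        raise ValueError("empty survival dataset")
    nll, designs = _negloglik_factory(data, spec, epsilon)
    theta = _params_to_theta(params, designs)
    v = nll(theta)
    return -float(v) if np.isfinite(v) else -np.inf


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class FitResult:
    spec: ModelSpec
    estimates: ParameterSet
    log_likelihood: float
    k: int
    aic: float
    converged: bool
    n_starts_used: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "id": self.spec.id,
            "coefficients": self.estimates.coefficients,
            "estimates": self.estimates.table().to_dict("records"),
            "log_likelihood": self.log_likelihood,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
        }


def count_free_parameters(spec: ModelSpec) -> int:
    """One baseline per free parameter plus one coefficient per extra
    covariate level (rank adds 2, video adds 1); gamma fixed at 1 adds 0."""
    k = 0
    for p in PARAM_NAMES:
        if p == "gamma" and spec.gamma_fixed_one:
            continue
        k += 1
        if p in spec.rank_on:
            k += 2
        if p in spec.video_on:
            k += 1
    return k


def _initial_theta(data, spec, designs):
    """Method-of-moments starting point: alpha from events per unit exposure,
    pi from the fraction of fish with any event, gamma = 1."""
    events = data["event"].sum()
    exposure = data["gap_time"].clip(lower=DEFAULT_EPSILON).sum()
    alpha0 = max(events, 0.5) / max(exposure, 1e-9)
    attempted = data.groupby("fish_id")["event"].max()
    pi0 = float(np.clip(attempted.mean(), 0.05, 0.95))
    init = ParameterSet.from_values(alpha0, 1.0, pi0,
                                    gamma_fixed_one=spec.gamma_fixed_one)
    return _params_to_theta(init, designs)


def fit_model(data: pd.DataFrame, spec: ModelSpec, *, n_starts: int = 10,
              seed: int = 0, tol: float = 1e-8,
              epsilon: float = DEFAULT_EPSILON) -> FitResult:
    """Maximum-likelihood fit of one covariate structure.

    Optimization is quasi-Newton (L-BFGS-B) on the unconstrained link scale
    (log alpha, log gamma, logit pi); the first start is a method-of-moments
    guess and the remaining ``n_starts - 1`` are seeded perturbations of it,
    keeping the best optimum found.

    A covariate level used by the spec that contains no events makes the
    corresponding parameters weakly identified; the fit proceeds but is
    flagged ``degenerate`` with a warning.
    """
    if data.empty:
        raise ValueError("empty survival dataset")
    nll, designs = _negloglik_factory(data, spec, epsilon)
    theta0 = _initial_theta(data, spec, designs)

    degenerate = False
    active = spec.rank_on | spec.video_on
    if "alpha" in active or "gamma" in active or "pi" in active:
        groups = []
        if spec.rank_on:
            groups.append("rank_group")
        if spec.video_on:
            groups.append("video")
        if groups:
            per_level = data.groupby(groups)["event"].sum()
            if (per_level == 0).any():
                degenerate = True
                warnings.warn(
                    f"{spec.id}: a covariate level has no events; estimates "
                    "for that level are weakly identified", stacklevel=2)

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    n_used = 0
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.5,
                                                          size=theta0.size)
        res = minimize(nll, start, method="L-BFGS-B",
                       options={"ftol": tol, "gtol": 1e-8, "maxiter": 500})
        n_used += 1
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)
    theta_hat = np.asarray(best.x, dtype=float)
    ll = -float(best.fun)
    k = count_free_parameters(spec)
    return FitResult(
        spec=spec,
        estimates=_theta_to_params(theta_hat, designs),
        log_likelihood=ll,
        k=k,
        aic=2.0 * k - 2.0 * ll,
        converged=converged,
        n_starts_used=n_used,
        degenerate=degenerate,
    )


def fit_grid(data: pd.DataFrame, *, n_starts: int = 3, seed: int = 0,
             tol: float = 1e-8,
             epsilon: float = DEFAULT_EPSILON) -> list[FitResult]:
    """Fit all 32 covariate structures and return them ranked by AIC.

    Grid fits default to fewer random restarts than a single-model fit: the
    moment-based start is reliable for these smooth likelihoods and the grid
    multiplies every extra start by 32.
    """
    fits = [fit_model(data, spec, n_starts=n_starts, seed=seed + i, tol=tol,
                      epsilon=epsilon)
            for i, spec in enumerate(enumerate_grid())]
    return select_by_aic(fits)


def select_by_aic(fits) -> list[FitResult]:
    """Rank fits by ascending AIC; ties broken by fewer parameters, then id."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    return sorted(fits, key=lambda f: (f.aic, f.k, int(f.spec.id[1:])))


def grid_table(fits) -> pd.DataFrame:
    """AIC comparison table over the grid, one row per model."""
    ranked = select_by_aic(fits)
    best_aic = ranked[0].aic
    rows = [(f.spec.id,
             "+".join(p for p in PARAM_NAMES if p in f.spec.rank_on),
             "+".join(p for p in PARAM_NAMES if p in f.spec.video_on),
             "1" if f.spec.gamma_fixed_one else "free",
             f.k, f.log_likelihood, f.aic, f.aic - best_aic)
            for f in sorted(fits, key=lambda f: int(f.spec.id[1:]))]
    return pd.DataFrame(rows, columns=[
        "model", "rank_on", "video_on", "gamma", "k",
        "log_likelihood", "aic", "delta_aic"])


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit survival estimate: values on a time grid plus the
    at-risk counts and censoring times needed to draw the usual staircase
    with tick marks."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


def kaplan_meier(data: pd.DataFrame, group_by=None) -> dict:
    """Kaplan-Meier curves of gap times, optionally per covariate group.

    Parameters
    ----------
    data
        Survival dataset from :func:`escapement.events.build_survival_data`.
    group_by
        Column name (e.g. ``"rank_group"``) to stratify on, or None for one
        pooled curve keyed ``"all"``.

    Returns
    -------
    dict mapping group label -> :class:`KMCurve`.
    """
    if data.empty:
        raise ValueError("empty survival dataset")
    groups = {"all": data} if group_by is None else dict(tuple(
        data.groupby(group_by, sort=True)))
    out = {}
    for label, sub in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["gap_time"], event_observed=sub["event"])
        table = kmf.event_table
        times = np.asarray(kmf.survival_function_.index, dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
        if times[0] != 0.0:
            times = np.insert(times, 0, 0.0)
            surv = np.insert(surv, 0, 1.0)
        at_risk = np.asarray(
            [int(table["at_risk"].loc[table.index <= t].iloc[-1])
             if (table.index <= t).any() else int(len(sub))
             for t in times])
        censor_times = np.sort(
            sub.loc[sub["event"] == 0, "gap_time"].to_numpy(float))
        out[label] = KMCurve(times, surv, at_risk, censor_times)
    return out
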