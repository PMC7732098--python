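"""Binomial (logit) regression of attempt success, with AIC model selection.

Whether an escapement attempt succeeds (the fish passes through a mesh) is
modelled per attempt as a Bernoulli outcome.  Candidate predictors are the
attempt rank (does success change with repeated attempts?), the video
sequence (beginning vs middle of the tow), and one optional user-supplied
binary attempt-level covariate.  All additive subsets of the available
covariates are fitted and ranked by AIC; under the null model the fitted
probability is exactly the sample success proportion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .events import rank_group as _rank_group

#: logit-scale cap applied when complete separation drives a coefficient
#: toward infinity
SEPARATION_CAP = 15.0


@dataclass
class GLMFit:
    """One fitted logistic model: coefficient estimates on the logit scale,
    fit statistics and per-attempt fitted probabilities."""

    formula: tuple
    coefficients: dict
    log_likelihood: float
    k: int
    aic: float
    fitted: np.ndarray
    converged: bool
    separated: bool = False

    @property
    def label(self) -> str:
        return " + ".join(self.formula) if self.formula else "null"


def build_success_dataset(attempts, extra=None,
                          extra_name: str = "extra") -> pd.DataFrame:
    """One row per attempt with outcome and covariates.

    ``extra`` optionally supplies the third, user-defined binary covariate as
    a sequence aligned with ``attempts``.
    """
    rows = [(int(a.success), _rank_group(a.rank), a.video_id)
            for a in attempts]
    df = pd.DataFrame(rows, columns=["success", "rank_group", "video"])
    if extra is not None:
        if len(extra) != len(df):
            raise ValueError("extra covariate length does not match attempts")
        df[extra_name] = np.asarray(extra, dtype=int)
    return df


def _design(dataset: pd.DataFrame, covariates):
    n = len(dataset)
    cols, names = [np.ones(n)], ["intercept"]
    for cov in covariates:
        if cov == "rank_group":
            cols += [(dataset["rank_group"] == "R2").to_numpy(float),
                     (dataset["rank_group"] == "R3plus").to_numpy(float)]
            names += ["rank_R2", "rank_R3plus"]
        elif cov == "video":
            cols.append((dataset["video"] == "V2").to_numpy(float))
            names.append("video_V2")
        else:
            if cov not in dataset.columns:
                raise KeyError(f"covariate {cov!r} not in dataset")
            cols.append(dataset[cov].to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    # unused factor levels yield all-zero dummies; drop them as any GLM
    # front-end would
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    return X[:, keep], [names[j] for j in keep]


def fit_logistic(dataset: pd.DataFrame, covariates=()) -> GLMFit:
    """Maximum-likelihood logit fit by iteratively reweighted least squares.

    Convergence is declared when the Bernoulli deviance changes by less than
    1e-8.  Under complete separation a coefficient diverges; it is capped at
    +/-15 on the logit scale and the fit flagged ``separated``.
    """
    covariates = tuple(covariates)
    y = dataset["success"].to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one success and one failure")
    X, names = _design(dataset, covariates)
    beta = np.zeros(X.shape[1])
    deviance = np.inf
    converged = False
    for _ in range(200):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, wx.T @ z)
        mu = expit(np.clip(X @ beta, -30, 30))
        new_dev = -2.0 * np.sum(y * np.log(np.maximum(mu, 1e-300))
                                + (1 - y) * np.log(np.maximum(1 - mu, 1e-300)))
        if abs(new_dev - deviance) < 1e-8:
            converged = True
            deviance = new_dev
            break
        deviance = new_dev

    separated = bool(np.any(np.abs(beta) > SEPARATION_CAP))
    if separated:
        warnings.warn(
            "complete or quasi-complete separation: coefficients capped at "
            f"+/-{SEPARATION_CAP} on the logit scale", stacklevel=2)
        beta = np.clip(beta, -SEPARATION_CAP, SEPARATION_CAP)

    mu = expit(np.clip(X @ beta, -30, 30))
    ll = float(np.sum(y * np.log(np.maximum(mu, 1e-300))
                      + (1 - y) * np.log(np.maximum(1 - mu, 1e-300))))
    k = X.shape[1]
    return GLMFit(
        formula=covariates,
        coefficients=dict(zip(names, beta.astype(float))),
        log_likelihood=ll,
        k=k,
        aic=2.0 * k - 2.0 * ll,
        fitted=mu,
        converged=converged,
        separated=separated,
    )


def success_model_grid(dataset: pd.DataFrame,
                       extra_name: str = "extra") -> list[GLMFit]:
    """Fit every additive subset of the available covariates, ranked by AIC.

    With the optional extra covariate present this is the 8-model set over
    (rank_group, video, extra); without it the grid restricts to the 4
    rank/video subsets with a warning.
    """
    covs = ["rank_group", "video"]
    if extra_name in dataset.columns:
        covs.append(extra_name)
    else:
        warnings.warn(
            f"no {extra_name!r} column: grid restricted to "
            "rank/video subsets (4 models)", stacklevel=2)
    fits = []
    for r in range(len(covs) + 1):
        for subset in itertools.combinations(covs, r):
            fits.append(fit_logistic(dataset, subset))
    return sorted(fits, key=lambda f: (f.aic, f.k, f.formula))


def grid_table(fits) -> pd.DataFrame:
    """AIC comparison table mirroring the ranked model set."""
    best = min(f.aic for f in fits)
    return pd.DataFrame(
        [(f.label, f.k, f.log_likelihood, f.aic, f.aic == best) for f in fits],
        columns=["formula", "k", "log_likelihood", "aic", "selected"])
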