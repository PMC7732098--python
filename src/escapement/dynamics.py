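"""Temporal dynamics of escapement attempts at the population level.

If each fish attempts at a constant individual rate (exponential gaps) and
fish enter the camera field as a homogeneous Poisson process, the cumulative
number of attempts over a video sequence grows linearly in expectation.
This module builds the cumulative step curve, fits straight lines to its
early portion, and wraps the observed curve in a Monte-Carlo envelope of
homogeneous-Poisson paths so that departures from linearity -- pulsed
arrivals, social facilitation -- show up as band exceedances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StepSeries:
    """Cumulative attempt count: sorted event times and the running count
    after each (ties collapse to one step of the tie's multiplicity)."""

    times: np.ndarray
    counts: np.ndarray

    @property
    def final_count(self) -> int:
        return int(self.counts[-1]) if len(self.counts) else 0

    def at(self, t) -> np.ndarray:
        """N(t): number of events with time <= t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        counts = np.concatenate([[0], self.counts])
        return counts[idx]


@dataclass
class LinearFit:
    slope: float          # attempts / second
    intercept: float
    window: tuple
    residual_sd: float
    n: int


@dataclass
class Envelope:
    """Pointwise Monte-Carlo band for cumulative homogeneous-Poisson paths."""

    grid: np.ndarray
    low: np.ndarray
    high: np.ndarray
    mean: np.ndarray
    rate: float
    n_sim: int
    observed_exceedance: float | None = None

    def exceedance_fraction(self, series: StepSeries) -> float:
        """Fraction of grid points where the observed curve leaves the band."""
        obs = series.at(self.grid)
        outside = (obs < self.low) | (obs > self.high)
        return float(outside.mean())

    def to_frame(self, series: StepSeries | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.grid, "band_low": self.low,
                           "band_high": self.high, "expected": self.mean})
        if series is not None:
            df.insert(1, "count", series.at(self.grid))
        return df


def cumulative_curve(attempts, video_id: str | None = None) -> StepSeries:
    """Cumulative number of attempts through time, optionally for one video.

    Times are seconds from the start of the video sequence.  An empty
    selection yields an empty series with count 0.
    """
    times = np.sort(np.asarray(
        [a.time for a in attempts
         if video_id is None or a.video_id == video_id], dtype=float))
    if times.size == 0:
        return StepSeries(np.array([]), np.array([]))
    uniq, mult = np.unique(times, return_counts=True)
    return StepSeries(uniq, np.cumsum(mult))


def windowed_slope(series: StepSeries, window_seconds: float = 30.0,
                   grid_step: float | None = None) -> LinearFit:
    """Ordinary least squares of cumulative count on time over an initial
    window.

    By default the regression uses the step function at its event times
    (the curve as plotted); pass ``grid_step`` to evaluate N(t) on a regular
    grid instead.  Requires at least two points in the window.
    """
    if grid_step is not None:
        x = np.arange(0.0, window_seconds + 1e-9, grid_step)
        y = series.at(x).astype(float)
    else:
        mask = series.times <= window_seconds
        x = series.times[mask]
        y = series.counts[mask].astype(float)
    if x.size < 2:
        raise ValueError(
            f"need >= 2 points in the first {window_seconds} s, got {x.size}")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    resid_sd = float(np.sqrt(np.sum(resid ** 2) / max(x.size - 2, 1)))
    return LinearFit(float(slope), float(intercept),
                     (0.0, float(window_seconds)), resid_sd, int(x.size))


def poisson_envelope(rate: float, duration: float, n_sim: int = 1000,
                     seed: int = 0, observed: StepSeries | None = None,
                     coverage: float = 0.95) -> Envelope:
    """Monte-Carlo pointwise band for the cumulative count of a homogeneous
    Poisson process.

    Simulates ``n_sim`` cumulative paths at the given rate on a 1-second
    grid and takes pointwise (1-coverage)/2 percentiles.  If an observed
    series is supplied, the fraction of grid points at which it leaves the
    band is stored on the returned envelope.  A same-process path should
    exceed a 95% band at only a few percent of grid points; a pulse of
    near-simultaneous attempts drives the fraction far higher.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if n_sim < 200:
        raise ValueError("n_sim must be >= 200 for stable percentiles")
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, float(duration) + 1e-9, 1.0)
    increments = rng.poisson(rate * np.diff(grid), size=(n_sim, grid.size - 1))
    paths = np.concatenate(
        [np.zeros((n_sim, 1), dtype=int), np.cumsum(increments, axis=1)],
        axis=1)
    tail = 100.0 * (1.0 - coverage) / 2.0
    low = np.percentile(paths, tail, axis=0)
    high = np.percentile(paths, 100.0 - tail, axis=0)
    env = Envelope(grid, low, high, rate * grid, float(rate), int(n_sim))
    if observed is not None:
        env.observed_exceedance = env.exceedance_fraction(observed)
    return env
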