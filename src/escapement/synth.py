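"""Synthetic ethogram generator.

Produces event logs with the statistical structure the analysis assumes --
Poisson (or pulsed) fish arrivals, short variable observation windows, a
cured fraction that never attempts, per-rank Weibull attempt gaps, Bernoulli
attempt success -- so that every downstream stage can be exercised and its
estimators checked against known truth without any video data.

Defaults reproduce the observed study conditions for gadoids meeting a
100 mm square-mesh cylinder in a trawl extension: roughly 100 fish per
5-minute sequence over two sequences, observation windows of mean 2.23 s
(sd 2.5 s), an 88% attempting fraction, exponential gaps with per-rank
rates (0.6, 0.29, 0.38) per second, and a 14.8% success probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .events import (AXIS_STATES, AttemptRecord, BehaviorInterval,
                     ObservationRecord, write_event_log)

#: seed of the reference fixture shipped with the package
FIXTURE_SEED = 20201211

#: starting-state weights of the behavior-state switcher, loosely shaped
#: like the observed time budgets (trawl-speed swimming, forward-facing,
#: upper-central positions); the switcher exists to exercise time-budget
#: code, not to model swimming
_STATE_WEIGHTS = {
    "speed": (0.05, 0.15, 0.60, 0.20),
    "orientation": (0.55, 0.30, 0.15),
    "vertical": (0.45, 0.40, 0.15),
    "horizontal": (0.33, 0.34, 0.33),
}


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic ethogram.

    Attributes
    ----------
    arrival_mode
        ``"homogeneous"`` for Poisson arrivals at ``arrival_rate`` fish/s,
        ``"pulsed"`` to add bursts given by ``pulses``.
    pulses
        Sequence of ``(time_s, n_fish)`` bursts; each burst's fish arrive
        within ``pulse_spread`` seconds of the pulse time.
    n_fish
        If set, overrides the Poisson draw with a fixed number of fish per
        video (arrival times still from the arrival process).
    obs_mean_s, obs_sd_s
        Natural-scale mean and sd of the lognormal observation-window
        duration, truncated to ``[obs_min_s, obs_max_s]``.
    obs_fixed_s
        If set, every fish gets this fixed window length instead (used to
        make censoring negligible in calibration checks).
    clamp_to_sequence
        Cut observation windows at the end of the video sequence (on by
        default; disable together with ``obs_fixed_s`` for effectively
        uncensored data).
    pi
        Attempting proportion.  Before every gap -- the first and each one
        after an attempt -- the fish stops attempting for good with
        probability ``1 - pi``, so each gap's survival curve asymptotes at
        ``1 - pi`` exactly as the mixture model assumes, and the fraction of
        fish ever attempting (under unlimited observation) is ``pi``.
    alpha_by_rank
        Weibull scale (1/s) for gap ranks 1, 2 and 3-plus; a fish past its
        third attempt keeps the 3-plus scale.
    gamma
        Weibull shape shared by all ranks (1 = exponential).
    success_p
        Probability that any attempt succeeds; success removes the fish.
    vertical_probs
        Attempt position distribution over (top, center, bottom); the
        default is top-biased as observed on upper-panel devices.
    informative_censoring
        Optional robustness toggle: attempting fish get windows shortened
        by 30%, violating the model's non-informative censoring assumption.
    """

    arrival_mode: str = "homogeneous"
    arrival_rate: float = 1.0 / 3.0          # ~100 fish per 300 s sequence
    pulses: tuple = ()
    pulse_spread: float = 2.0
    n_fish: int | None = None
    sequence_duration: float = 300.0
    n_videos: int = 2
    obs_mean_s: float = 2.23
    obs_sd_s: float = 2.5
    obs_min_s: float = 0.25
    obs_max_s: float = 25.0
    obs_fixed_s: float | None = None
    clamp_to_sequence: bool = True
    pi: float = 0.88
    alpha_by_rank: tuple = (0.6, 0.29, 0.38)
    gamma: float = 1.0
    success_p: float = 0.148
    vertical_probs: tuple = (0.69, 0.21, 0.10)
    horizontal_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    state_switch_rate: float = 0.5           # behavior changes per second
    simulate_states: bool = True             # off for large calibration runs
    informative_censoring: bool = False

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if not 0.0 <= self.success_p <= 1.0:
            raise ValueError("success_p must lie in [0, 1]")
        if any(a <= 0 for a in self.alpha_by_rank) or self.gamma <= 0:
            raise ValueError("alpha and gamma must be > 0")
        if self.arrival_mode not in ("homogeneous", "pulsed"):
            raise ValueError(f"unknown arrival_mode {self.arrival_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pulses", "alpha_by_rank", "vertical_probs",
                    "horizontal_probs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(p) if isinstance(p, list) else p
                                 for p in raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _lognormal_params(mean: float, sd: float):
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _draw_window(rng, cfg: SimulationConfig) -> float:
    if cfg.obs_fixed_s is not None:
        return float(cfg.obs_fixed_s)
    mu, sigma = _lognormal_params(cfg.obs_mean_s, cfg.obs_sd_s)
    for _ in range(1000):
        d = float(rng.lognormal(mu, sigma))
        if cfg.obs_min_s <= d <= cfg.obs_max_s:
            return d
    return float(np.clip(d, cfg.obs_min_s, cfg.obs_max_s))


def _weibull_gap(rng, alpha: float, gamma: float) -> float:
    # S(t) = exp(-(alpha t)^gamma)  <=>  t = E^(1/gamma) / alpha, E ~ Exp(1)
    return float(rng.exponential() ** (1.0 / gamma) / alpha)


def _arrival_plan(rng, cfg: SimulationConfig) -> list:
    """Per-fish arrival descriptors: ``None`` for a background arrival
    (uniform over the sequence, drawn from the fish's own stream) or the
    pulse time for a pulse member.  Only the population size comes from the
    shared arrival stream, so enlarging it never perturbs existing fish."""
    if cfg.n_fish is not None:
        n = int(cfg.n_fish)
    else:
        n = int(rng.poisson(cfg.arrival_rate * cfg.sequence_duration))
    plan: list = [None] * n
    if cfg.arrival_mode == "pulsed":
        for t, size in cfg.pulses:
            plan.extend([float(t)] * int(size))
    return plan


def _round_time(x: float) -> float:
    # all emitted times are rounded to 1 ms -- far below the ~40 ms video
    # frame resolution; keeps CSV output compact and round-trippable
    return round(float(x), 3)


def _simulate_states(rng, cfg: SimulationConfig, fish_id: str,
                     entry: float, exit_: float) -> list[BehaviorInterval]:
    intervals = []
    for axis, states in AXIS_STATES.items():
        probs = np.asarray(_STATE_WEIGHTS[axis], dtype=float)
        probs = probs / probs.sum()
        state = states[int(rng.choice(len(states), p=probs))]
        t = entry
        while t < exit_ - 1e-6:
            dwell = rng.exponential(1.0 / cfg.state_switch_rate)
            end = min(_round_time(t + dwell), exit_)
            if end > t:
                intervals.append(
                    BehaviorInterval(fish_id, axis, state, t, end))
            t = end
            others = [s for s in states if s != state]
            state = others[int(rng.choice(len(others)))]
    return intervals


def simulate_ethogram(config: SimulationConfig | None = None, seed: int = 0):
    """Generate one synthetic ethogram.

    Each fish owns an independent random sub-stream keyed by (seed, video,
    fish index), so enlarging the population or reordering videos never
    perturbs the fish already generated.  Attempts falling beyond a fish's
    observation window are discarded, which is exactly how right censoring
    arises in the real data; a successful attempt ends the fish's window at
    the attempt time.

    Returns the validated ``(observations, states, attempts)`` triple in the
    events-module schema.
    """
    cfg = config or SimulationConfig()
    observations, states, attempts = [], [], []
    for v in range(1, cfg.n_videos + 1):
        video = f"V{v}"
        arrival_rng = np.random.default_rng([seed, v])
        plan = _arrival_plan(arrival_rng, cfg)
        for i, pulse_time in enumerate(plan):
            rng = np.random.default_rng([seed, v, i])
            fish_id = f"{video}_F{i:04d}"
            if pulse_time is None:
                entry = rng.uniform(0.0, cfg.sequence_duration)
            else:
                entry = pulse_time + cfg.pulse_spread * rng.random()
            window = _draw_window(rng, cfg)
            attempting = rng.random() < cfg.pi
            if cfg.informative_censoring and attempting:
                window *= 0.7
            entry = _round_time(entry)
            exit_ = _round_time(entry + window)
            if cfg.clamp_to_sequence:
                exit_ = min(exit_, cfg.sequence_duration)
            if exit_ - entry <= 0.05:
                continue
            fish_attempts = []
            t, rank = entry, 1
            while attempting:
                alpha = cfg.alpha_by_rank[min(rank, 3) - 1]
                t = _round_time(t + _weibull_gap(rng, alpha, cfg.gamma))
                if t > exit_:
                    break
                success = rng.random() < cfg.success_p
                vert = AXIS_STATES["vertical"][
                    int(rng.choice(3, p=np.asarray(cfg.vertical_probs)))]
                horiz = AXIS_STATES["horizontal"][
                    int(rng.choice(3, p=np.asarray(cfg.horizontal_probs)))]
                fish_attempts.append(
                    AttemptRecord(fish_id, video, rank, t, vert, horiz,
                                  success))
                if success:
                    exit_ = t
                    break
                rank += 1
                # the mixture's cure mass applies to every gap: after an
                # attempt the fish gives up for good with probability 1 - pi
                attempting = rng.random() < cfg.pi
            observations.append(
                ObservationRecord(fish_id, video, entry, exit_, "gadoid"))
            if cfg.simulate_states:
                states.extend(
                    _simulate_states(rng, cfg, fish_id, entry, exit_))
            attempts.extend(fish_attempts)
    return observations, states, attempts


# ---------------------------------------------------------------------------
# Reference fixture

def reference_fixture(seed: int = FIXTURE_SEED):
    """The small deterministic dataset shipped with the package: default
    study conditions, about 200 fish over two 300-s videos.  Regenerable
    bit-identically from its seed."""
    return simulate_ethogram(SimulationConfig(), seed=seed)


def write_fixture(directory, seed: int = FIXTURE_SEED) -> None:
    obs, states, attempts = reference_fixture(seed)
    write_event_log(directory, obs, states, attempts)


def fixture_path() -> Path:
    """Path of the packaged fixture CSV directory."""
    return Path(resources.files("escapement") / "data" / "fixture")
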