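"""Ethogram event logs: reading, validation, survival-data construction and
descriptive statistics.

An ethogram here is a timed record of fish observed by an underwater camera
mounted in the extension of a bottom trawl.  Each fish is followed from its
entry into the field of view until it disappears (an *observation window*),
its swimming behavior is annotated as state intervals on four axes (speed,
orientation, vertical position, horizontal position), and each escapement
attempt -- a voluntary swim toward the netting with snout contact -- is
logged with its time, rank, position and outcome.

The central product of this module is the gap-time survival dataset: for
every fish, the elapsed time from entry to its first attempt, between
successive attempts, and (when the fish leaves without attempting again) the
right-censored tail from the last event to its exit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

# ---------------------------------------------------------------------------
# Category vocabularies

AXIS_STATES: dict[str, tuple[str, ...]] = {
    "speed": ("immobility", "slow", "medium", "fast"),
    "orientation": ("forward", "lateral", "aft"),
    "vertical": ("top", "center", "bottom"),
    "horizontal": ("left", "center", "right"),
}

RANK_LABELS = ("R1", "R2", "R3plus")
VIDEO_LABELS = ("V1", "V2")

OBSERVATIONS_COLUMNS = ["fish_id", "video_id", "entry_time", "exit_time", "taxon"]
STATES_COLUMNS = ["fish_id", "axis", "state", "start", "end"]
ATTEMPTS_COLUMNS = ["fish_id", "video_id", "rank", "time",
                    "vertical", "horizontal", "success"]


def rank_group(rank: int) -> str:
    """Map an attempt rank to its pooled covariate level (ranks >= 3 pooled)."""
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    return RANK_LABELS[min(int(rank), 3) - 1]


class SchemaError(ValueError):
    """An input file does not match the documented column schema."""


class ValidationError(ValueError):
    """One or more records violate the ethogram invariants.

    The individual messages (one per violation, with fish id and row number
    where available) are kept in :attr:`errors`.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} validation error(s):\n" + "\n".join(self.errors)
        )


# ---------------------------------------------------------------------------
# Record types

@dataclass(frozen=True)
class ObservationRecord:
    """One fish's presence window in the camera field, in seconds from the
    start of its video sequence."""

    fish_id: str
    video_id: str
    entry_time: float
    exit_time: float
    taxon_label: str = ""

    @property
    def duration(self) -> float:
        return self.exit_time - self.entry_time


@dataclass(frozen=True)
class BehaviorInterval:
    """A maximal interval during which a fish holds one behavioral state on
    one axis (speed / orientation / vertical / horizontal)."""

    fish_id: str
    axis: str
    state: str
    start: float
    end: float


@dataclass(frozen=True)
class AttemptRecord:
    """One escapement attempt: instant, rank within the fish, position on the
    netting, and whether the fish passed through a mesh."""

    fish_id: str
    video_id: str
    rank: int
    time: float
    vertical_pos: str
    horizontal_pos: str
    success: bool


# ---------------------------------------------------------------------------
# Validation

def validate_records(observations, intervals, attempts) -> list[str]:
    """Check every ethogram invariant; return the list of violation messages.

    Checks, per record type:

    * observations -- positive duration, unique fish ids, known video label;
    * behavior intervals -- positive length, known axis/state, containment in
      the fish's window, non-overlap per fish and axis;
    * attempts -- known fish, matching video, consecutive ranks from 1,
      increasing times inside the window, at most one success and only as the
      fish's last attempt.

    Tied attempt times within a fish are allowed (broken by input order) but
    draw a warning.
    """
    errors: list[str] = []
    by_id: dict[str, ObservationRecord] = {}
    for i, o in enumerate(observations):
        if o.fish_id in by_id:
            errors.append(f"observations row {i}: duplicate fish_id {o.fish_id!r}")
        else:
            by_id[o.fish_id] = o
        if o.video_id not in VIDEO_LABELS:
            errors.append(
                f"observations row {i}: unknown video_id {o.video_id!r} "
                f"for fish {o.fish_id!r}")
        if not o.exit_time > o.entry_time:
            errors.append(
                f"observations row {i}: fish {o.fish_id!r} has non-positive "
                f"observation duration ({o.entry_time}..{o.exit_time})")

    seen_axis: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for i, iv in enumerate(intervals):
        if iv.axis not in AXIS_STATES:
            errors.append(f"states row {i}: unknown axis {iv.axis!r}")
            continue
        if iv.state not in AXIS_STATES[iv.axis]:
            errors.append(
                f"states row {i}: unknown state {iv.state!r} on axis {iv.axis!r}")
        if not iv.start < iv.end:
            errors.append(
                f"states row {i}: fish {iv.fish_id!r} interval start >= end")
        obs = by_id.get(iv.fish_id)
        if obs is None:
            errors.append(f"states row {i}: unknown fish_id {iv.fish_id!r}")
        elif iv.start < obs.entry_time - 1e-9 or iv.end > obs.exit_time + 1e-9:
            errors.append(
                f"states row {i}: fish {iv.fish_id!r} interval "
                f"[{iv.start}, {iv.end}] outside its window "
                f"[{obs.entry_time}, {obs.exit_time}]")
        seen_axis.setdefault((iv.fish_id, iv.axis), []).append((iv.start, iv.end))
    for (fid, axis), spans in seen_axis.items():
        spans.sort()
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0 - 1e-9:
                errors.append(
                    f"fish {fid!r}: overlapping {axis} intervals "
                    f"[{s0}, {e0}] and [{s1}, {e1}]")

    per_fish: dict[str, list[AttemptRecord]] = {}
    for i, a in enumerate(attempts):
        obs = by_id.get(a.fish_id)
        if obs is None:
            errors.append(f"attempts row {i}: unknown fish_id {a.fish_id!r}")
            continue
        if a.video_id != obs.video_id:
            errors.append(
                f"attempts row {i}: fish {a.fish_id!r} video {a.video_id!r} "
                f"does not match observation video {obs.video_id!r}")
        if not (obs.entry_time - 1e-9 <= a.time <= obs.exit_time + 1e-9):
            errors.append(
                f"attempts row {i}: fish {a.fish_id!r} attempt at t={a.time} "
                f"outside its window [{obs.entry_time}, {obs.exit_time}]")
        if a.vertical_pos not in AXIS_STATES["vertical"]:
            errors.append(
                f"attempts row {i}: unknown vertical position {a.vertical_pos!r}")
        if a.horizontal_pos not in AXIS_STATES["horizontal"]:
            errors.append(
                f"attempts row {i}: unknown horizontal position "
                f"{a.horizontal_pos!r}")
        per_fish.setdefault(a.fish_id, []).append(a)

    for fid, rows in per_fish.items():
        ranks = [a.rank for a in rows]
        if ranks != list(range(1, len(rows) + 1)):
            errors.append(
                f"fish {fid!r}: attempt ranks {ranks} are not consecutive from 1")
        times = [a.time for a in rows]
        for t0, t1 in zip(times, times[1:]):
            if t1 < t0:
                errors.append(f"fish {fid!r}: attempt times out of order")
                break
            if t1 == t0:
                warnings.warn(
                    f"fish {fid!r}: tied attempt times at t={t0}; "
                    "order taken from input", stacklevel=2)
        n_success = sum(a.success for a in rows)
        if n_success > 1:
            errors.append(f"fish {fid!r}: more than one successful attempt")
        elif n_success == 1 and not rows[-1].success:
            errors.append(
                f"fish {fid!r}: successful attempt is not the fish's last")
    return errors


# ---------------------------------------------------------------------------
# CSV reader / writer

def _require_columns(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _resolve_paths(path):
    """Accept a directory holding the three standard CSVs, or a triple of
    explicit file paths (observations, states, attempts)."""
    if isinstance(path, (tuple, list)):
        obs_p, states_p, att_p = (Path(p) for p in path)
    else:
        d = Path(path)
        if not d.exists():
            raise FileNotFoundError(d)
        obs_p = d / "observations.csv"
        states_p = d / "states.csv"
        att_p = d / "attempts.csv"
    return obs_p, states_p, att_p


def read_event_log(path):
    """Read and validate an ethogram event log.

    Parameters
    ----------
    path
        Directory containing ``observations.csv``, ``states.csv`` and
        ``attempts.csv``, or a 3-tuple of file paths in that order.

    Returns
    -------
    (observations, intervals, attempts)
        Lists of :class:`ObservationRecord`, :class:`BehaviorInterval` and
        :class:`AttemptRecord`, fully validated.

    Raises
    ------
    SchemaError
        If a file lacks a required column.
    ValidationError
        If any record violates an ethogram invariant; all violations are
        reported together with their row numbers.
    """
    obs_p, states_p, att_p = _resolve_paths(path)
    obs_df = pd.read_csv(obs_p, dtype={"fish_id": str, "video_id": str})
    states_df = pd.read_csv(states_p, dtype={"fish_id": str})
    att_df = pd.read_csv(att_p, dtype={"fish_id": str, "video_id": str})
    _require_columns(obs_df, OBSERVATIONS_COLUMNS, obs_p.name)
    _require_columns(states_df, STATES_COLUMNS, states_p.name)
    _require_columns(att_df, ATTEMPTS_COLUMNS, att_p.name)

    observations = [
        ObservationRecord(r.fish_id, r.video_id, float(r.entry_time),
                          float(r.exit_time),
                          "" if pd.isna(r.taxon) else str(r.taxon))
        for r in obs_df.itertuples()
    ]
    intervals = [
        BehaviorInterval(r.fish_id, str(r.axis), str(r.state),
                         float(r.start), float(r.end))
        for r in states_df.itertuples()
    ]
    attempts = [
        AttemptRecord(r.fish_id, r.video_id, int(r.rank), float(r.time),
                      str(r.vertical), str(r.horizontal), _as_bool(r.success))
        for r in att_df.itertuples()
    ]
    errors = validate_records(observations, intervals, attempts)
    if errors:
        raise ValidationError(errors)
    return observations, intervals, attempts


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError([f"cannot interpret success value {x!r} as boolean"])


def write_event_log(directory, observations, intervals, attempts) -> None:
    """Write the three standard CSVs; inverse of :func:`read_event_log`."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(o.fish_id, o.video_id, o.entry_time, o.exit_time, o.taxon_label)
         for o in observations], columns=OBSERVATIONS_COLUMNS,
    ).to_csv(d / "observations.csv", index=False)
    pd.DataFrame(
        [(iv.fish_id, iv.axis, iv.state, iv.start, iv.end)
         for iv in intervals], columns=STATES_COLUMNS,
    ).to_csv(d / "states.csv", index=False)
    pd.DataFrame(
        [(a.fish_id, a.video_id, a.rank, a.time, a.vertical_pos,
          a.horizontal_pos, a.success) for a in attempts],
        columns=ATTEMPTS_COLUMNS,
    ).to_csv(d / "attempts.csv", index=False)


def read_boris_export(path, mapping):
    """Shim for tab-separated aggregated-event exports of behavioral
    annotation tools (BORIS-style).

    The export is one row per event with subject / behavior / start / stop
    columns; ``mapping`` (a YAML/JSON file path or a dict) names those
    columns and declares which behavior labels carry which meaning::

        columns:
          fish_id: Subject
          video_id: Media
          behavior: Behavior
          start: "Start (s)"
          stop: "Stop (s)"
          modifiers: Modifiers
        observation_behavior: in_view
        attempt_behavior: escape_attempt
        success_modifier: success
        state_axes:
          speed: [immobility, slow, medium, fast]
          orientation: [forward, lateral, aft]
          vertical: [top, center, bottom]
          horizontal: [left, center, right]

    Attempt position modifiers are read as ``vertical|horizontal`` from the
    modifiers column (missing parts default to ``center``).  Ranks are
    assigned by time order within each fish.  Returns the same validated
    triple as :func:`read_event_log`.
    """
    if not isinstance(mapping, dict):
        with open(mapping) as fh:
            mapping = yaml.safe_load(fh)
    cols = mapping["columns"]
    df = pd.read_csv(path, sep="\t", dtype={cols["fish_id"]: str})
    needed = [cols[k] for k in ("fish_id", "behavior", "start", "stop")]
    _require_columns(df, needed, Path(path).name)

    state_axes = mapping.get("state_axes", AXIS_STATES)
    state_of = {s: ax for ax, states in state_axes.items() for s in states}
    obs_behavior = mapping["observation_behavior"]
    att_behavior = mapping["attempt_behavior"]
    success_mod = mapping.get("success_modifier", "success")
    video_col = cols.get("video_id")
    mod_col = cols.get("modifiers")

    observations, intervals, raw_attempts = [], [], []
    for r in df.to_dict("records"):
        video = str(r[video_col]) if video_col else "V1"
        behavior = str(r[cols["behavior"]])
        start = float(r[cols["start"]])
        fid = str(r[cols["fish_id"]])
        if behavior == obs_behavior:
            observations.append(
                ObservationRecord(fid, video, start, float(r[cols["stop"]])))
        elif behavior == att_behavior:
            mods = str(r[mod_col]) if mod_col else ""
            if mods == "nan":
                mods = ""
            parts = [p.strip() for p in mods.split("|")] if mods else []
            vert = next((p for p in parts if p in AXIS_STATES["vertical"]),
                        "center")
            horiz = next((p for p in parts if p in AXIS_STATES["horizontal"]),
                         "center")
            raw_attempts.append(
                (fid, video, start, vert, horiz, success_mod in parts))
        elif behavior in state_of:
            intervals.append(
                BehaviorInterval(fid, state_of[behavior], behavior,
                                 start, float(r[cols["stop"]])))
        else:
            raise ValidationError(
                [f"unmapped behavior label {behavior!r} in {path}"])

    attempts = []
    raw_attempts.sort(key=lambda t: (t[0], t[2]))
    rank_counter: dict[str, int] = {}
    for fid, video, t, vert, horiz, success in raw_attempts:
        rank_counter[fid] = rank_counter.get(fid, 0) + 1
        attempts.append(
            AttemptRecord(fid, video, rank_counter[fid], t, vert, horiz,
                          success))
    errors = validate_records(observations, intervals, attempts)
    if errors:
        raise ValidationError(errors)
    return observations, intervals, attempts


# ---------------------------------------------------------------------------
# Gap-time survival dataset

def build_survival_data(observations, attempts) -> pd.DataFrame:
    """Build the recurrent gap-time survival dataset.

    For each fish the clock starts at its entry into the field of view and is
    reset to zero after every attempt.  Each observed attempt contributes one
    event row whose gap time is the elapsed time since the previous reset; if
    the fish's last attempt failed and it later left the field, the remaining
    time to exit is a right-censored row; a fish with no attempts contributes
    a single censored row spanning its whole window.  A successful attempt
    removes the fish (it escaped), so no censored tail follows it.

    Returns
    -------
    pandas.DataFrame
        Columns ``fish_id``, ``video``, ``rank_group`` (R1 / R2 / R3plus),
        ``gap_time`` (seconds) and ``event`` (1 = attempt, 0 = censored).
    """
    per_fish: dict[str, list[AttemptRecord]] = {}
    for a in attempts:
        per_fish.setdefault(a.fish_id, []).append(a)
    rows = []
    for o in observations:
        clock = o.entry_time
        fish_attempts = sorted(per_fish.get(o.fish_id, []), key=lambda a: a.rank)
        succeeded = False
        for a in fish_attempts:
            gap = a.time - clock
            if gap < 0:
                raise ValidationError(
                    [f"fish {o.fish_id!r}: negative gap for rank {a.rank} "
                     f"(attempt at t={a.time} before clock {clock})"])
            rows.append((o.fish_id, o.video_id, rank_group(a.rank), gap, 1))
            clock = a.time
            succeeded = a.success
        if not succeeded:
            tail = o.exit_time - clock
            if tail < 0:
                raise ValidationError(
                    [f"fish {o.fish_id!r}: attempt after exit time"])
            rows.append((o.fish_id, o.video_id,
                         rank_group(len(fish_attempts) + 1), tail, 0))
    return pd.DataFrame(
        rows, columns=["fish_id", "video", "rank_group", "gap_time", "event"])


# ---------------------------------------------------------------------------
# Time budgets

@dataclass
class TimeBudget:
    """Per-fish time budgets and their population summary.

    ``per_fish`` has one row per (fish, axis, state) with the percentage of
    that fish's annotated time on that axis spent in the state.  States never
    visited by a fish appear with 0 so population means are taken over the
    full state vocabulary.
    """

    per_fish: pd.DataFrame

    def summary(self, axis: str) -> pd.DataFrame:
        """Mean and sample sd (ddof=1) of the per-fish percentages, across
        the fish that have the axis annotated."""
        sub = self.per_fish[self.per_fish["axis"] == axis]
        if sub.empty:
            raise ValueError(f"no fish with annotated axis {axis!r}")
        out = (sub.groupby("state", sort=False)["percent"]
                  .agg(mean="mean", sd=lambda s: s.std(ddof=1))
                  .reset_index())
        order = {s: i for i, s in enumerate(AXIS_STATES[axis])}
        return (out.sort_values("state", key=lambda s: s.map(order))
                   .reset_index(drop=True))


def compute_time_budget(intervals, observations) -> TimeBudget:
    """Percentage of each fish's annotated time spent in each state, per axis.

    Gaps in the annotation are allowed: percentages are normalized over the
    annotated (not the total) time, so they always sum to 100 per fish and
    axis.  A fish with zero annotated time on an axis is excluded from that
    axis with a warning.
    """
    per_axis: dict[tuple[str, str], dict[str, float]] = {}
    for iv in intervals:
        d = per_axis.setdefault((iv.fish_id, iv.axis), {})
        d[iv.state] = d.get(iv.state, 0.0) + (iv.end - iv.start)
    rows = []
    for o in observations:
        for axis, states in AXIS_STATES.items():
            d = per_axis.get((o.fish_id, axis))
            if d is None:
                continue
            total = sum(d.values())
            if total <= 0:
                warnings.warn(
                    f"fish {o.fish_id!r}: zero annotated time on axis "
                    f"{axis!r}; excluded", stacklevel=2)
                continue
            for state in states:
                rows.append((o.fish_id, axis, state,
                             100.0 * d.get(state, 0.0) / total))
    return TimeBudget(pd.DataFrame(
        rows, columns=["fish_id", "axis", "state", "percent"]))


# ---------------------------------------------------------------------------
# Attempt-position test

def position_chi_square(attempts, axis: str):
    """Pearson goodness-of-fit test of attempt positions against a uniform
    distribution over the axis's categories.

    Returns ``(statistic, df, p_value)`` with ``df = categories - 1`` and an
    upper-tail chi-square p-value.  The null of uniform use of the axis is an
    interpretation choice; a contingency-style comparison between axes is a
    different question and is not what this computes.
    """
    if axis not in ("vertical", "horizontal"):
        raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")
    if not len(attempts):
        raise ValueError("empty attempt set")
    attr = "vertical_pos" if axis == "vertical" else "horizontal_pos"
    categories = AXIS_STATES[axis]
    counts = np.array(
        [sum(1 for a in attempts if getattr(a, attr) == c) for c in categories],
        dtype=float)
    stat, p = stats.chisquare(counts)
    return float(stat), len(categories) - 1, float(p)


def records_to_frame(records) -> pd.DataFrame:
    """Convenience: a list of record dataclasses as a DataFrame."""
    return pd.DataFrame([asdict(r) for r in records])
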