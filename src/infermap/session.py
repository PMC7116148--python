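"""In-memory containers binding the streams of one recording session.

A *session* covers one or more recording days on a single clock (seconds).
It binds sorted spike times per unit, the trial table of cue events, the
animal's position trace, the rest/task epoch table, and (optionally) a
wide-band LFP trace with a ripple-free reference channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .errors import SchemaError

TRIAL_COLUMNS = [
    "trial_id", "day", "block", "stage", "cue", "set",
    "onset", "offset", "outcome_time", "correct",
]

EPOCH_COLUMNS = ["day", "context", "start", "end"]


@dataclass
class LfpTrace:
    """LFP detection channel plus ripple-free reference, single clock."""

    fs: float
    t0: float
    data: np.ndarray   # detection channel, uV (arbitrary scale)
    ref: np.ndarray    # reference channel, same length

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.size) / self.fs

    def __post_init__(self) -> None:
        if len(self.data) != len(self.ref):
            raise SchemaError("lfp: data and ref must have equal length")


@dataclass
class PositionTrace:
    """Animal position sampled at a fixed camera rate.

    Speed is the backward-difference step length divided by the sample
    period (the first sample repeats the next one so all streams have
    equal length): each sample reports how fast the animal moved into its
    current position.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    outcome_area: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise SchemaError("position: t, x, y must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise SchemaError("position: timestamps must be strictly increasing")

    @property
    def speed(self) -> np.ndarray:
        """Instantaneous speed in cm/s (backward difference)."""
        if len(self.t) < 2:
            return np.zeros(len(self.t))
        dt = np.diff(self.t)
        v = np.hypot(np.diff(self.x), np.diff(self.y)) / dt
        return np.insert(v, 0, v[0])

    def in_outcome_area(self) -> np.ndarray:
        """Boolean mask of samples inside the outcome-area polygon."""
        path = MplPath(np.asarray(self.outcome_area, float))
        pts = np.column_stack([self.x, self.y])
        return path.contains_points(pts)

    def slice(self, start: float, end: float) -> "PositionTrace":
        m = (self.t >= start) & (self.t < end)
        return PositionTrace(self.t[m], self.x[m], self.y[m], self.outcome_area)


@dataclass
class SessionData:
    """All streams of one recorded session on a single clock."""

    spikes: dict[int, np.ndarray]          # unit id -> sorted spike times (s)
    trials: pd.DataFrame                   # TRIAL_COLUMNS
    position: PositionTrace
    epochs: pd.DataFrame                   # EPOCH_COLUMNS; rest/task blocks
    lfp: LfpTrace | None = None
    licks: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.spikes)

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def days(self) -> list[int]:
        return sorted(self.trials["day"].unique()) if len(self.trials) else []

    def day_span(self, day: int) -> tuple[float, float]:
        ep = self.epochs[self.epochs["day"] == day]
        if not len(ep):
            tr = self.trials[self.trials["day"] == day]
            return float(tr["onset"].min()), float(tr["offset"].max())
        return float(ep["start"].min()), float(ep["end"].max())

    def spikes_in(self, unit: int, start: float, end: float) -> np.ndarray:
        s = self.spikes[unit]
        return s[np.searchsorted(s, start): np.searchsorted(s, end)]

    def mean_rate(self, unit: int, intervals: np.ndarray) -> float:
        """Mean firing rate (Hz) of ``unit`` over ``intervals`` (n x 2)."""
        intervals = np.atleast_2d(np.asarray(intervals, float))
        total = float(np.sum(intervals[:, 1] - intervals[:, 0]))
        if total <= 0:
            return 0.0
        n = sum(len(self.spikes_in(unit, a, b)) for a, b in intervals)
        return n / total

    def validate(self) -> None:
        """Cross-stream consistency checks; raise :class:`SchemaError`."""
        for uid, s in self.spikes.items():
            if len(s) > 1 and np.any(np.diff(s) < 0):
                raise SchemaError(f"spikes: unit {uid} times are not sorted")
        tr = self.trials
        missing = [c for c in TRIAL_COLUMNS if c not in tr.columns]
        if missing:
            raise SchemaError(f"trials: missing columns {missing}")
        bad = tr.index[tr["offset"] <= tr["onset"]]
        if len(bad):
            raise SchemaError(f"trials: offset <= onset at row {bad[0]}")
        srt = tr.sort_values("onset")
        overlap = srt["onset"].values[1:] < srt["offset"].values[:-1] - 1e-9
        if overlap.any():
            row = srt.index[1:][overlap][0]
            raise SchemaError(f"trials: overlapping trial at row {row}")
        wrong_set = tr["set"] != tr["cue"].str[-1].astype(int)
        if wrong_set.any():
            raise SchemaError(
                f"trials: set inconsistent with cue at row {tr.index[wrong_set][0]}"
            )
        if len(tr) and len(self.position.t):
            t0, t1 = self.position.t[0], self.position.t[-1]
            if tr["onset"].min() < t0 - 1e-6 or tr["offset"].max() > t1 + 1e-6:
                raise SchemaError("trials: trial windows exceed position coverage")


def trials_of(trials: pd.DataFrame, *, stage: str | None = None,
              cue: str | None = None, day: int | None = None,
              set_: int | None = None) -> pd.DataFrame:
    """Convenience filter over the trial table."""
    m = np.ones(len(trials), bool)
    if stage is not None:
        m &= (trials["stage"] == stage).values
    if cue is not None:
        m &= (trials["cue"] == cue).values
    if day is not None:
        m &= (trials["day"] == day).values
    if set_ is not None:
        m &= (trials["set"] == set_).values
    return trials[m]
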