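"""Trial-level behavioral quantities.

Three groups of operations:

* **decision-point filtering** -- the decision point of a trial is the
  latest time at which the animal's speed is below 5 cm/s before it first
  enters the outcome area on that trial.  Neural data after the decision
  point are censored downstream to decouple cue coding from approach and
  dispenser location.
* **reward-seeking bias** -- per-day set 1 minus set 2 scores of time spent
  in the outcome area (or licking) in cue-locked windows.
* **bootstrap effect sizes** -- estimation-statistics style mean
  differences with bias-corrected-and-accelerated (BCa) 95% confidence
  intervals from bootstrap resamples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DECISION_SPEED
from .errors import CoverageError, ValidationError
from .session import PositionTrace, trials_of

log = logging.getLogger(__name__)

#: sentinel for "the animal entered the area but never slowed below
#: threshold first": the trial is excluded from filtered analyses
UNDEFINED = math.nan

MEASURES = ("inference_window_20s", "conditioning_cue_window",
            "visit_fraction", "lick_count")


# --------------------------------------------------------------------- #
# decision point
# --------------------------------------------------------------------- #

def decision_point(trial, pos: PositionTrace,
                   speed: np.ndarray | None = None,
                   in_area: np.ndarray | None = None,
                   threshold: float = DECISION_SPEED) -> float | None:
    """Decision point of one trial, in seconds.

    Returns ``None`` when the animal never enters the outcome area during
    the trial (the whole trial is kept), and ``nan`` when it enters without
    ever slowing below ``threshold`` first (the trial is excluded from
    filtered analyses).  Entry means an outside->inside transition of the
    outcome-area polygon; a trial that starts with the animal already
    inside has no entry.
    """
    on, off = float(trial["onset"]), float(trial["offset"])
    if len(pos.t) == 0 or pos.t[0] > on + 1e-9 or pos.t[-1] < off - 1e-9:
        raise CoverageError(
            f"trial window [{on:.2f}, {off:.2f}] not covered by position trace"
        )
    if speed is None:
        speed = pos.speed
    if in_area is None:
        in_area = pos.in_outcome_area()
    i0 = int(np.searchsorted(pos.t, on, side="left"))
    i1 = int(np.searchsorted(pos.t, off, side="right"))
    a = in_area[i0:i1]
    if a.size == 0 or a.all():
        return None
    entries = np.flatnonzero(~a[:-1] & a[1:]) + 1
    if a[0]:
        # already inside at trial start: only later re-entries count
        first_out = int(np.argmax(~a))
        entries = entries[entries > first_out]
    if entries.size == 0:
        return None
    entry = int(entries[0])
    slow = np.flatnonzero(speed[i0:i0 + entry] < threshold)
    if slow.size == 0:
        return UNDEFINED
    return float(pos.t[i0 + slow[-1]])


def decision_points(trials: pd.DataFrame, pos: PositionTrace,
                    threshold: float = DECISION_SPEED) -> dict[int, float | None]:
    """Decision point per trial id (vector version of :func:`decision_point`)."""
    speed = pos.speed
    in_area = pos.in_outcome_area()
    out: dict[int, float | None] = {}
    for _, tr in trials.iterrows():
        out[int(tr["trial_id"])] = decision_point(
            tr, pos, speed=speed, in_area=in_area, threshold=threshold)
    return out


# --------------------------------------------------------------------- #
# reward-seeking bias
# --------------------------------------------------------------------- #

def _area_fraction(pos_t, in_area, start, end) -> float:
    m = (pos_t >= start) & (pos_t < end)
    if not m.any():
        return 0.0
    return float(in_area[m].mean())


def reward_seeking_bias(trials: pd.DataFrame, pos: PositionTrace,
                        measure: str = "inference_window_20s",
                        licks: np.ndarray | None = None,
                        post_window: float = 20.0) -> pd.DataFrame:
    """Per-day reward-seeking bias, set 1 minus set 2.

    Measures
    --------
    ``inference_window_20s``
        Percent time in the outcome area during the ``post_window`` seconds
        after auditory-cue offset, on inference-test trials.
    ``conditioning_cue_window``
        Percent time in the outcome area during the visual cue, prior to
        outcome delivery, on conditioning trials.
    ``visit_fraction``
        Percent of trials with at least one in-area sample in the measure
        window (same windows as above, picked by trial stage).
    ``lick_count``
        Lick rate (events/s) in the measure window; needs ``licks``.

    Returns a frame with one row per day: day, set1, set2, bias, n1, n2.
    """
    if measure not in MEASURES:
        raise ValidationError(f"measure must be one of {MEASURES}")
    if measure == "lick_count" and licks is None:
        raise ValidationError("measure 'lick_count' requires lick event times")
    in_area = pos.in_outcome_area()

    if measure == "conditioning_cue_window":
        sel = trials_of(trials, stage="conditioning")
        sel = sel[sel["cue"].str.startswith("Y")]
        windows = list(zip(sel["onset"], sel["offset"]))
    else:
        sel = trials_of(trials, stage="inference_test")
        windows = list(zip(sel["offset"], sel["offset"] + post_window))

    scores = []
    for (start, end) in windows:
        if measure == "lick_count":
            n = np.searchsorted(licks, end) - np.searchsorted(licks, start)
            scores.append(n / max(end - start, 1e-9))
        else:
            frac = _area_fraction(pos.t, in_area, start, end)
            if measure == "visit_fraction":
                scores.append(100.0 * (frac > 0))
            else:
                scores.append(100.0 * frac)
    sel = sel.assign(score=scores)

    rows = []
    for day, grp in sel.groupby("day"):
        s1 = grp[grp["set"] == 1]["score"]
        s2 = grp[grp["set"] == 2]["score"]
        if not len(s1) or not len(s2):
            log.warning("day %s omitted from bias: missing trials for a set", day)
            continue
        rows.append(dict(day=day, set1=s1.mean(), set2=s2.mean(),
                         bias=s1.mean() - s2.mean(), n1=len(s1), n2=len(s2)))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# bootstrap effect size
# --------------------------------------------------------------------- #

@dataclass
class EffectEstimate:
    """A group difference with its bootstrap sampling distribution."""

    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    distribution: np.ndarray
    paired: bool = False
    degenerate: bool = False

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"EffectEstimate(point={self.point:.4g}, "
                f"95% CI [{self.ci_low:.4g}, {self.ci_high:.4g}], "
                f"n_boot={self.n_boot}{', degenerate' if self.degenerate else ''})")

    def to_dict(self) -> dict:
        return dict(point=self.point, ci_low=self.ci_low, ci_high=self.ci_high,
                    n_boot=self.n_boot, paired=self.paired,
                    degenerate=self.degenerate)


def bootstrap_effect_size(a, b, n_boot: int = 10_000,
                          seed: int | None = None,
                          paired: bool = False) -> EffectEstimate:
    """Mean difference ``mean(a) - mean(b)`` with a BCa 95% CI.

    The interval is bias-corrected and accelerated, the method used by
    estimation-statistics (DABEST-style) plots.  With ``paired=True``,
    resampling keeps index-aligned pairs together.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("a and b must be non-empty")
    if paired and a.size != b.size:
        raise ValidationError("paired groups must have equal length")
    if n_boot < 1000:
        log.warning("n_boot=%d is below the recommended 1000", n_boot)
    point = float(a.mean() - b.mean())
    rng = np.random.default_rng(seed)

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return EffectEstimate(point, point, point, n_boot, seed,
                              np.full(n_boot, point), paired, degenerate=True)

    res = stats.bootstrap(
        (a, b),
        lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
        n_resamples=n_boot, paired=paired, vectorized=True,
        confidence_level=0.95, method="BCa", random_state=rng,
    )
    dist = np.asarray(res.bootstrap_distribution)
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not np.isfinite(lo) or not np.isfinite(hi):
        # BCa degenerates when the jackknife variance vanishes
        lo = hi = point
        return EffectEstimate(point, lo, hi, n_boot, seed, dist, paired,
                              degenerate=True)
    return EffectEstimate(point, lo, hi, n_boot, seed, dist, paired)


def bootstrap_mean(values, n_boot: int = 10_000,
                   seed: int | None = None) -> EffectEstimate:
    """One-sample BCa bootstrap of the mean (difference from zero)."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValidationError("values must be non-empty")
    point = float(values.mean())
    if np.ptp(values) == 0:
        return EffectEstimate(point, point, point, n_boot, seed,
                              np.full(n_boot, point), degenerate=True)
    rng = np.random.default_rng(seed)
    res = stats.bootstrap(
        (values,), lambda x, axis=-1: np.mean(x, axis=axis),
        n_resamples=n_boot, vectorized=True, confidence_level=0.95,
        method="BCa", random_state=rng,
    )
    dist = np.asarray(res.bootstrap_distribution)
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not np.isfinite(lo) or not np.isfinite(hi):
        return EffectEstimate(point, point, point, n_boot, seed, dist,
                              degenerate=True)
    return EffectEstimate(point, lo, hi, n_boot, seed, dist)
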