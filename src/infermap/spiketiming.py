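"""Pairwise spike-timing analyses during cue presentation.

For a directed pair (trigger, target), both spike trains are restricted to
the relevant cue windows and a 200 ms window (1 ms bins) is laid around
every trigger spike.  From the per-bin target spike counts we derive

* a cross-correlogram with the per-bin joint spiking probability expressed
  as a change from the mean over the 50 ms pre-trigger baseline, and
* a Z-scored spike-triggered average (STA); pairs whose target fires fewer
  than 20 spikes across all trigger windows are excluded, not silently
  dropped.

The after-minus-before STA asymmetry (mean Z over (0, +100] ms minus mean
over [-100, 0) ms) quantifies the temporal order of the pair; its group
effect uses the same bias-corrected bootstrap as the behavioral effect
sizes.

Trigger spikes near a cue-window edge keep a truncated window: each lag
bin is normalized by the number of triggers whose window actually covers
that bin, which avoids edge bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import EffectEstimate, bootstrap_mean
from .errors import ValidationError


def _ranges(i0: np.ndarray, i1: np.ndarray) -> np.ndarray:
    """Concatenate arange(i0[k], i1[k]) for all k (vectorized)."""
    counts = (i1 - i0).astype(int)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, int)
    nz = counts > 0
    a, c = i0[nz].astype(int), counts[nz]
    steps = np.ones(total, int)
    seg = np.concatenate([[0], np.cumsum(c)[:-1]])
    # steps[seg[k]] must make the cumsum jump from the last value of segment
    # k-1 (which is a[k-1] + c[k-1] - 1) to a[k]
    prev_last = np.concatenate([[0], a[:-1] + c[:-1] - 1])
    steps[seg] = a - prev_last
    return np.cumsum(steps)


def _restrict(spikes: np.ndarray, windows: np.ndarray | None) -> np.ndarray:
    if windows is None or len(windows) == 0:
        return np.asarray(spikes, float)
    spikes = np.asarray(spikes, float)
    w = np.atleast_2d(np.asarray(windows, float))
    order = np.argsort(w[:, 0])
    starts, ends = w[order, 0], w[order, 1]
    idx = np.searchsorted(starts, spikes, side="right") - 1
    ok = (idx >= 0) & (spikes < ends[np.clip(idx, 0, None)])
    return spikes[ok]


def _window_of(spikes: np.ndarray, windows: np.ndarray | None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Start/end of the cue window containing each spike."""
    if windows is None or len(windows) == 0:
        return (np.full(spikes.shape, -np.inf), np.full(spikes.shape, np.inf))
    w = np.atleast_2d(np.asarray(windows, float))
    order = np.argsort(w[:, 0])
    starts, ends = w[order, 0], w[order, 1]
    idx = np.searchsorted(starts, spikes, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    return starts[idx], ends[idx]


@dataclass
class CrossCorrelogram:
    """Lag histogram of target spikes around trigger spikes."""

    lags_ms: np.ndarray           # bin centers
    counts: np.ndarray            # target spikes per lag bin
    n_triggers: np.ndarray        # triggers contributing per bin
    joint_p: np.ndarray           # counts / contributing triggers
    baseline: float               # mean joint_p over the pre-trigger baseline
    delta_joint_p: np.ndarray     # joint_p - baseline
    n_trigger_spikes: int
    empty: bool = False


def cross_correlogram(trigger_spikes, target_spikes,
                      cue_windows: np.ndarray | None = None,
                      window_ms: float = 100.0, bin_ms: float = 1.0,
                      baseline_ms: float = 50.0) -> CrossCorrelogram:
    """Target-relative-to-trigger lag histogram with joint-probability change.

    The joint probability of a bin is the mean target spike count per
    trigger in that 1 ms lag bin; the change is expressed relative to the
    average over the ``baseline_ms`` window before the trigger.
    """
    trig = np.sort(_restrict(trigger_spikes, cue_windows))
    targ = np.sort(_restrict(target_spikes, cue_windows))
    w = window_ms / 1000.0
    b = bin_ms / 1000.0
    nb = int(round(2 * window_ms / bin_ms))
    edges = -w + b * np.arange(nb + 1)
    centers = 1000.0 * (edges[:-1] + edges[1:]) / 2.0

    if trig.size == 0:
        z = np.zeros(nb)
        return CrossCorrelogram(centers, z.copy(), z.copy(), z.copy(),
                                0.0, z.copy(), 0, empty=True)

    i0 = np.searchsorted(targ, trig - w)
    i1 = np.searchsorted(targ, trig + w)
    idx = _ranges(i0, i1)
    diffs = targ[idx] - np.repeat(trig, i1 - i0)
    counts, _ = np.histogram(diffs, bins=edges)

    ws, we = _window_of(trig, cue_windows)
    lo = np.sort(ws - trig)          # valid lag lower limits per trigger
    hi = np.sort(we - trig)
    # a trigger covers lag bin j when lo <= left edge and right edge <= hi
    n_trig = (np.searchsorted(lo, edges[:-1] + 1e-12, side="right")
              - np.searchsorted(hi, edges[1:] - 1e-12, side="left"))
    n_trig = np.maximum(n_trig, 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        joint = np.where(n_trig > 0, counts / np.maximum(n_trig, 1), 0.0)
    base_mask = (centers >= -baseline_ms) & (centers < 0)
    baseline = float(joint[base_mask].mean()) if base_mask.any() else 0.0
    return CrossCorrelogram(centers, counts.astype(float), n_trig.astype(float),
                            joint, baseline, joint - baseline, int(trig.size))


@dataclass
class StaResult:
    """Z-scored spike-triggered average for one directed pair."""

    pair: tuple[int, int]          # (trigger, target) unit ids
    lags_ms: np.ndarray
    z: np.ndarray                  # Z-scored rate per 1 ms bin
    rate: np.ndarray               # Hz per bin
    counts: np.ndarray
    n_trigger_spikes: int
    n_target_spikes: int           # target spikes across all trigger windows
    included: bool
    zscore_mode: str = "sta"

    def asymmetry(self) -> float:
        """Mean Z after the trigger minus mean Z before it."""
        after = self.lags_ms > 0
        before = self.lags_ms < 0
        return float(self.z[after].mean() - self.z[before].mean())

    def smoothed(self, k: int = 5) -> np.ndarray:
        """Moving average for display only; never feeds statistics."""
        kernel = np.ones(k) / k
        return np.convolve(self.z, kernel, mode="same")


def spike_triggered_average(trigger_spikes, target_spikes,
                            cue_windows: np.ndarray | None = None,
                            pair: tuple[int, int] = (-1, -1),
                            window_ms: float = 100.0, bin_ms: float = 1.0,
                            min_target_spikes: int = 20,
                            zscore: str = "sta") -> StaResult:
    """Z-scored per-bin target rate around trigger spikes.

    ``zscore='sta'`` normalizes by the mean/SD across the 200 bins of the
    same STA; ``zscore='poisson'`` instead scores each bin's count against
    a homogeneous Poisson expectation at the target's cue-window rate.
    Pairs with fewer than ``min_target_spikes`` target spikes across all
    trigger windows are returned with ``included=False``.
    """
    if zscore not in ("sta", "poisson"):
        raise ValidationError("zscore must be 'sta' or 'poisson'")
    cc = cross_correlogram(trigger_spikes, target_spikes, cue_windows,
                           window_ms, bin_ms, baseline_ms=50.0)
    b = bin_ms / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(cc.n_triggers > 0, cc.counts / (cc.n_triggers * b), 0.0)
    n_target = int(cc.counts.sum())
    included = (not cc.empty) and n_target >= min_target_spikes

    if zscore == "sta":
        sd = rate.std()
        z = (rate - rate.mean()) / sd if sd > 0 else np.zeros_like(rate)
    else:
        targ = _restrict(target_spikes, cue_windows)
        total_t = (float(np.sum(np.diff(np.atleast_2d(cue_windows), axis=1)))
                   if cue_windows is not None and len(cue_windows) else np.inf)
        lam = len(targ) / total_t if np.isfinite(total_t) and total_t > 0 else 0.0
        expect = lam * cc.n_triggers * b
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(expect > 0, (cc.counts - expect) / np.sqrt(expect), 0.0)
    return StaResult(pair=pair, lags_ms=cc.lags_ms, z=z, rate=rate,
                     counts=cc.counts, n_trigger_spikes=cc.n_trigger_spikes,
                     n_target_spikes=n_target, included=included,
                     zscore_mode=zscore)


def sta_asymmetry(stas: list[StaResult], n_boot: int = 10_000,
                  seed: int | None = None) -> tuple[np.ndarray, EffectEstimate]:
    """Group after-minus-before effect across included pairs.

    Returns the per-pair asymmetries and the bias-corrected bootstrap
    estimate of their mean.
    """
    included = [s for s in stas if s.included]
    if len(included) < 2:
        raise ValidationError("need >= 2 included pairs for a group effect")
    vals = np.array([s.asymmetry() for s in included])
    return vals, bootstrap_mean(vals, n_boot=n_boot, seed=seed)
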