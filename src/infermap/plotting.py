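"""Minimal matplotlib views of the core result objects.

All functions take an optional ``ax`` and return it, so they compose into
multi-panel figures; nothing here feeds any statistic.
"""

from __future__ import annotations

import numpy as np
from matplotlib.patches import Rectangle


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_rsm(rsm, ax=None, cmap="viridis"):
    """Heatmap of a cross-stimulus RSM with the within cells outlined."""
    ax = _ax(ax)
    vals = rsm.values
    imshow = ax.imshow(vals.values, cmap=cmap, vmin=-1, vmax=1)
    ax.set_xticks(range(len(vals.columns)), vals.columns)
    ax.set_yticks(range(len(vals.index)), vals.index)
    mask = rsm.within_mask().values
    for (i, j) in zip(*np.nonzero(mask)):
        ax.add_patch(Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                               edgecolor="red", lw=2))
    ax.figure.colorbar(imshow, ax=ax, label="Pearson r")
    return ax


def plot_sta(sta, ax=None, smooth_ms: int = 5):
    """Z-scored spike-triggered average with its display-only smoothing."""
    ax = _ax(ax)
    ax.plot(sta.lags_ms, sta.z, color="0.7", lw=0.8, label="raw")
    ax.plot(sta.lags_ms, sta.smoothed(smooth_ms), color="C0",
            label=f"{smooth_ms} ms moving average")
    ax.axvline(0, color="k", ls=":")
    ax.set_xlabel("lag from trigger spike (ms)")
    ax.set_ylabel("Z-scored rate")
    ax.legend(frameon=False)
    return ax


def plot_effect(effect, ax=None, label: str = "effect"):
    """Estimation-statistics view: bootstrap distribution + 95% CI."""
    ax = _ax(ax)
    ax.hist(effect.distribution, bins=60, density=True, color="0.8")
    ax.axvline(effect.point, color="C1", label=f"{label}: {effect.point:.3g}")
    ax.axvline(effect.ci_low, color="C0", ls="--")
    ax.axvline(effect.ci_high, color="C0", ls="--",
               label=f"95% CI [{effect.ci_low:.3g}, {effect.ci_high:.3g}]")
    ax.axvline(0.0, color="k", ls=":")
    ax.set_xlabel(label)
    ax.legend(frameon=False)
    return ax


def plot_correlogram(cc, ax=None):
    """Joint-probability change relative to the pre-trigger baseline."""
    ax = _ax(ax)
    ax.bar(cc.lags_ms, cc.delta_joint_p, width=1.0, color="C0")
    ax.axvline(0, color="k", ls=":")
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("joint probability - baseline")
    return ax
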