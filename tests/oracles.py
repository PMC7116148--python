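"""Brute-force reference implementations used as independent oracles.

These are deliberately naive (double loops, event-by-event counting) and
share no code with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def sta_counts_bruteforce(trigger, target, windows, window_ms=100.0,
                          bin_ms=1.0):
    """Per-lag-bin target spike counts and contributing-trigger counts.

    Double loop over (trigger spike, target spike) pairs, both restricted
    to the cue windows; a trigger contributes to a lag bin only when its
    whole bin lies inside the trigger's own cue window.
    """
    def in_win(t):
        for (a, b) in windows:
            if a <= t < b:
                return (a, b)
        return None

    w = window_ms / 1000.0
    bs = bin_ms / 1000.0
    nb = int(round(2 * window_ms / bin_ms))
    edges = -w + bs * np.arange(nb + 1)
    counts = np.zeros(nb)
    n_trig = np.zeros(nb)
    for tt in trigger:
        win = in_win(tt)
        if win is None:
            continue
        for j in range(nb):
            if win[0] - tt <= edges[j] + 1e-12 and edges[j + 1] <= win[1] - tt + 1e-12:
                n_trig[j] += 1
        for ts in target:
            if in_win(ts) is None:
                continue
            d = ts - tt
            if -w <= d < w:
                j = int(np.floor((d + w) / bs))
                j = min(j, nb - 1)
                counts[j] += 1
    return counts, n_trig


def rsm_bruteforce(test_data, train_data):
    """Per-pair Pearson correlations via scipy, one pair at a time."""
    from scipy.stats import pearsonr
    nt = test_data.shape[1]
    nr = train_data.shape[1]
    out = np.empty((nt, nr))
    for i in range(nt):
        for j in range(nr):
            out[i, j] = pearsonr(test_data[:, i], train_data[:, j])[0]
    return out


def coactivation_bruteforce(event_spikes, units, n_events_early, rates_early,
                            rates_late, exclude_units=()):
    """Event-by-event p_hat counting.

    ``event_spikes`` is a list (one entry per SWR, early events first) of
    {unit: spike count}; returns (p_early, p_late).
    """
    def coactive(ev):
        if any(ev.get(u, 0) >= 1 for u in exclude_units):
            return False
        return all(ev.get(u, 0) >= 1 for u in units)

    early = event_spikes[:n_events_early]
    late = event_spikes[n_events_early:]
    n_e = sum(coactive(ev) for ev in early)
    n_l = sum(coactive(ev) for ev in late)
    f_e = float(np.mean([rates_early[u] for u in units]))
    f_l = float(np.mean([rates_late[u] for u in units]))
    return (n_e / len(early)) / f_e, (n_l / len(late)) / f_l


def mean_rate_contrast(spikes, windows, t_end):
    """Rate inside the given windows minus rate elsewhere (Hz)."""
    windows = np.atleast_2d(np.asarray(windows, float))
    t_in = float(np.sum(windows[:, 1] - windows[:, 0]))
    n_in = 0
    for t in spikes:
        for a, b in windows:
            if a <= t < b:
                n_in += 1
                break
    t_out = t_end - t_in
    n_out = len(spikes) - n_in
    return n_in / t_in - n_out / t_out
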