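"""Sharp-wave/ripple detection and SWR coactivation analyses.

Detection follows the standard ripple pipeline: band-pass the detection
channel (135-250 Hz), subtract a ripple-free reference to cancel
common-mode noise, take the RMS power envelope, and mark events where the
envelope exceeds the background mean by 7 SD during immobility
(speed < 1.5 cm/s).  Background statistics are computed over immobility
samples only.  Event edges extend to 2-SD crossings; events closer than a
merge gap are merged and very short ones dropped (field-standard
conventions, exposed as parameters).

Coactivation of a unit tuple across SWRs is summarized by the normalized
joint-firing probability

    p_hat = (n / N) / f_bar

where ``n`` is the number of SWRs in the epoch in which every member
fired, ``N`` the total number of SWRs in the epoch, and ``f_bar`` the
average of the members' mean firing rates in that epoch.  The early
(days 1-4) vs late (days 5-8) contrast ``p_hat_diff = p_hat_late -
p_hat_early`` is tested with bootstrap estimation, a set x day two-way
ANOVA with Tukey post hoc contrasts, and a permutation control that
shuffles which SWRs contain the first unit's spikes while holding the
second unit fixed (preserving both units' firing rates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .behavior import EffectEstimate, bootstrap_mean
from .config import IMMOBILITY_SPEED
from .errors import ValidationError
from .session import LfpTrace, SessionData

log = logging.getLogger(__name__)

EARLY_DAYS = (1, 2, 3, 4)
LATE_DAYS = (5, 6, 7, 8)


# --------------------------------------------------------------------- #
# detection
# --------------------------------------------------------------------- #

@dataclass
class SwrSet:
    """Detected (or ground-truth) ripple events."""

    events: pd.DataFrame     # start, end, peak_sd, day, context, source
    source: str = "detected"

    def __len__(self) -> int:
        return len(self.events)

    def intervals(self) -> np.ndarray:
        return self.events[["start", "end"]].values

    @classmethod
    def from_truth(cls, swr: pd.DataFrame) -> "SwrSet":
        ev = swr.copy()
        ev["peak_sd"] = np.nan
        ev["source"] = "ground_truth"
        return cls(ev, source="ground_truth")


def detect_swrs(lfp: LfpTrace, speed_t: np.ndarray, speed: np.ndarray,
                band: tuple[float, float] = (135.0, 250.0),
                threshold_sd: float = 7.0, edge_sd: float = 2.0,
                min_duration: float = 0.02, merge_gap: float = 0.01,
                immobility_speed: float = IMMOBILITY_SPEED,
                rms_window: float = 0.02,
                epochs: pd.DataFrame | None = None) -> SwrSet:
    """Detect ripples on the common-mode-subtracted, band-passed LFP.

    Raises when the sampling rate cannot support the band; returns an
    empty set (with a warning) when the animal is never immobile.
    """
    fs = lfp.fs
    if fs < 2 * band[1]:
        raise ValidationError(
            f"lfp sampling rate {fs} Hz too low for band {band}"
        )
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(lfp.data, float)) \
        - signal.sosfiltfilt(sos, np.asarray(lfp.ref, float))
    win = max(int(round(rms_window * fs)), 1)
    env = np.sqrt(ndimage.uniform_filter1d(filt ** 2, size=win))

    t = lfp.times
    v = np.interp(t, np.asarray(speed_t, float), np.asarray(speed, float))
    immobile = v < immobility_speed
    if not immobile.any():
        log.warning("no immobility below %.2f cm/s; returning empty set",
                    immobility_speed)
        return SwrSet(pd.DataFrame(
            columns=["start", "end", "peak_sd", "day", "context", "source"]))

    mu = env[immobile].mean()
    sd = env[immobile].std()
    if sd == 0:
        return SwrSet(pd.DataFrame(
            columns=["start", "end", "peak_sd", "day", "context", "source"]))
    above_hi = (env > mu + threshold_sd * sd) & immobile
    above_lo = env > mu + edge_sd * sd

    # contiguous low-threshold regions that contain a high-threshold sample
    lab, n_lab = ndimage.label(above_lo)
    if n_lab == 0:
        return SwrSet(pd.DataFrame(
            columns=["start", "end", "peak_sd", "day", "context", "source"]))
    hit_labels = np.unique(lab[above_hi])
    hit_labels = hit_labels[hit_labels > 0]
    slices = ndimage.find_objects(lab)
    raw = []
    for lb in hit_labels:
        sl = slices[lb - 1][0]
        raw.append((sl.start, sl.stop))
    raw.sort()

    merged: list[list[int]] = []
    gap = int(round(merge_gap * fs))
    for s0, s1 in raw:
        if merged and s0 - merged[-1][1] <= gap:
            merged[-1][1] = s1
        else:
            merged.append([s0, s1])

    rows = []
    for s0, s1 in merged:
        dur = (s1 - s0) / fs
        if dur < min_duration:
            continue
        peak = (env[s0:s1].max() - mu) / sd
        rows.append(dict(start=t[s0], end=t[min(s1, len(t) - 1)],
                         peak_sd=peak, day=np.nan, context="", source="detected"))
    ev = pd.DataFrame(rows, columns=["start", "end", "peak_sd", "day",
                                     "context", "source"])
    if epochs is not None and len(ev):
        for i, r in ev.iterrows():
            mid = (r["start"] + r["end"]) / 2.0
            hit = epochs[(epochs["start"] <= mid) & (epochs["end"] > mid)]
            if len(hit):
                ev.at[i, "day"] = hit.iloc[0]["day"]
                ev.at[i, "context"] = hit.iloc[0]["context"]
    return SwrSet(ev)


# --------------------------------------------------------------------- #
# participation
# --------------------------------------------------------------------- #

@dataclass
class ParticipationMatrix:
    """Event x unit spike counts within SWR bounds."""

    counts: np.ndarray             # events x units
    units: list[int]
    events: pd.DataFrame           # aligned with rows of counts

    @property
    def participation(self) -> np.ndarray:
        return self.counts >= 1

    def unit_col(self, unit: int) -> int:
        return self.units.index(unit)

    def event_mask_days(self, days) -> np.ndarray:
        return self.events["day"].isin(list(days)).values


def participation_matrix(session: SessionData, swrs: SwrSet,
                         context: str | None = None) -> ParticipationMatrix:
    ev = swrs.events
    if context is not None:
        ev = ev[ev["context"] == context]
    ev = ev.reset_index(drop=True)
    units = session.unit_ids
    counts = np.zeros((len(ev), len(units)), int)
    starts = ev["start"].values
    ends = ev["end"].values
    for j, u in enumerate(units):
        s = session.spikes[u]
        counts[:, j] = np.searchsorted(s, ends) - np.searchsorted(s, starts)
    return ParticipationMatrix(counts, units, ev)


# --------------------------------------------------------------------- #
# normalized joint-firing probability
# --------------------------------------------------------------------- #

@dataclass
class CoactivationResult:
    """Early/late normalized joint-firing probabilities for one tuple."""

    units: tuple[int, ...]
    label: str
    n_early: int
    N_early: int
    f_early: float
    p_early: float
    n_late: int
    N_late: int
    f_late: float
    p_late: float

    @property
    def p_diff(self) -> float:
        return self.p_late - self.p_early


def epoch_rates(session: SessionData, days, scope: str = "day") -> dict[int, float]:
    """Mean firing rate per unit over the given recording days.

    ``scope='day'`` uses whole-day time, ``scope='task'`` only task epochs.
    """
    ep = session.epochs[session.epochs["day"].isin(list(days))]
    if scope == "task":
        ep = ep[ep["context"] == "task"]
    if not len(ep):
        return {u: 0.0 for u in session.unit_ids}
    iv = ep[["start", "end"]].values
    return {u: session.mean_rate(u, iv) for u in session.unit_ids}


def coactivation_probability(part: ParticipationMatrix, units: tuple[int, ...],
                             rates_early: dict[int, float],
                             rates_late: dict[int, float],
                             early_days=EARLY_DAYS, late_days=LATE_DAYS,
                             exclude_units: tuple[int, ...] = (),
                             label: str = "") -> CoactivationResult | None:
    """The p_hat formula for one unit tuple; ``None`` when skipped.

    ``exclude_units``: joint firing is only counted in SWRs where none of
    these units fired (the "in absence of Yn" doublet variant).
    Tuples never coactive in any SWR, or with a zero-rate member, are
    skipped with a log message.
    """
    cols = [part.unit_col(u) for u in units]
    joint = part.participation[:, cols].all(axis=1)
    if exclude_units:
        ex_cols = [part.unit_col(u) for u in exclude_units]
        joint &= ~part.participation[:, ex_cols].any(axis=1)
    e_mask = part.event_mask_days(early_days)
    l_mask = part.event_mask_days(late_days)
    n_e, N_e = int(joint[e_mask].sum()), int(e_mask.sum())
    n_l, N_l = int(joint[l_mask].sum()), int(l_mask.sum())
    if n_e + n_l == 0:
        log.debug("tuple %s never coactive; skipped", units)
        return None
    f_e = float(np.mean([rates_early.get(u, 0.0) for u in units]))
    f_l = float(np.mean([rates_late.get(u, 0.0) for u in units]))
    if f_e <= 0 or f_l <= 0 or N_e == 0 or N_l == 0:
        log.info("tuple %s skipped: zero epoch rate or no events", units)
        return None
    return CoactivationResult(units, label, n_e, N_e, f_e, (n_e / N_e) / f_e,
                              n_l, N_l, f_l, (n_l / N_l) / f_l)


def build_tuples(ensembles, cues: tuple[str, ...],
                 max_tuples: int | None = None) -> list[tuple[int, ...]]:
    """All cross-products of single-ensemble members of the given cues.

    Units in more than one cue ensemble are excluded so each member
    provides a non-overlapping representation of one cue.
    """
    pools = [ensembles.single(c) for c in cues]
    if any(not p for p in pools):
        return []
    out = [tuple(t) for t in product(*pools) if len(set(t)) == len(t)]
    return out[:max_tuples] if max_tuples else out


def triplet_coactivation(part: ParticipationMatrix, ensembles,
                         cues: tuple[str, ...],
                         rates_early: dict[int, float],
                         rates_late: dict[int, float],
                         early_days=EARLY_DAYS, late_days=LATE_DAYS,
                         exclude_cue: str | None = None,
                         label: str = "",
                         max_tuples: int | None = None
                         ) -> list[CoactivationResult]:
    """p_hat for every tuple drawn from the given cue ensembles.

    ``cues=('X1','Y1','Z1')`` gives the set-1 triplets; ``('X1','Z1')``
    the doublets regardless of Y; ``('X1','Z1')`` with
    ``exclude_cue='Y1'`` the doublets in the absence of Y-ensemble
    activity (all Y1-ensemble units must stay silent in the counted SWRs).
    """
    excl: tuple[int, ...] = ()
    if exclude_cue is not None:
        excl = tuple(ensembles.single(exclude_cue))
    results = []
    for tup in build_tuples(ensembles, cues, max_tuples):
        r = coactivation_probability(part, tup, rates_early, rates_late,
                                     early_days, late_days, excl,
                                     label=label or "+".join(cues))
        if r is not None:
            results.append(r)
    return results


# --------------------------------------------------------------------- #
# group statistics: bootstrap + two-way ANOVA with Tukey post hoc
# --------------------------------------------------------------------- #

@dataclass
class CoactivationStats:
    effect_set1: EffectEstimate          # bootstrap of mean p_diff, set 1
    effect_set2: EffectEstimate
    anova: pd.DataFrame                  # set x epoch two-way ANOVA table
    interaction_F: float
    interaction_p: float
    tukey: pd.DataFrame
    long: pd.DataFrame                   # tidy p_hat table underlying the tests
    permutation_p: float | None = None   # optional permutation-F p-value

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([dict(
            set1_p_diff=self.effect_set1.point,
            set1_ci=(self.effect_set1.ci_low, self.effect_set1.ci_high),
            set2_p_diff=self.effect_set2.point,
            set2_ci=(self.effect_set2.ci_low, self.effect_set2.ci_high),
            interaction_F=self.interaction_F,
            interaction_p=self.interaction_p,
        )])


def _interaction_F(long: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    fit = ols("phat ~ C(set_id) * C(epoch)", data=long).fit()
    table = anova_lm(fit, typ=2)
    inter = table.loc["C(set_id):C(epoch)"]
    return float(inter["F"]), float(inter["PR(>F)"]), table


def coactivation_anova(results_set1: list[CoactivationResult],
                       results_set2: list[CoactivationResult],
                       n_boot: int = 10_000, seed: int | None = None,
                       n_perm_F: int = 0) -> CoactivationStats:
    """Bootstrap effects plus set x day(epoch) ANOVA with Tukey post hoc.

    Observations are per-tuple p_hat values, one per epoch.  An empty
    design cell raises.  ``n_perm_F > 0`` adds a permutation-F p-value for
    the interaction (group labels permuted, add-one rule).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = []
    for set_id, results in ((1, results_set1), (2, results_set2)):
        for k, r in enumerate(results):
            rows.append(dict(set_id=set_id, epoch="early", phat=r.p_early,
                             tuple_id=f"s{set_id}_{k}"))
            rows.append(dict(set_id=set_id, epoch="late", phat=r.p_late,
                             tuple_id=f"s{set_id}_{k}"))
    long = pd.DataFrame(rows)
    for set_id, epoch in product((1, 2), ("early", "late")):
        cell = long[(long["set_id"] == set_id) & (long["epoch"] == epoch)]
        if len(cell) < 2:
            raise ValidationError(
                f"design cell set {set_id} / {epoch} has {len(cell)} < 2 tuples"
            )

    eff1 = bootstrap_mean(np.array([r.p_diff for r in results_set1]),
                          n_boot=n_boot, seed=seed)
    eff2 = bootstrap_mean(np.array([r.p_diff for r in results_set2]),
                          n_boot=n_boot,
                          seed=None if seed is None else seed + 1)

    F, p, table = _interaction_F(long)
    groups = long["set_id"].astype(str) + "_" + long["epoch"]
    tukey_res = pairwise_tukeyhsd(long["phat"].values, groups.values)
    tukey = pd.DataFrame(tukey_res.summary().data[1:],
                         columns=tukey_res.summary().data[0])

    perm_p = None
    if n_perm_F > 0:
        rng = np.random.default_rng(seed)
        labels = long[["set_id", "epoch"]].values
        count = 0
        for _ in range(n_perm_F):
            idx = rng.permutation(len(long))
            shuf = long.copy()
            shuf[["set_id", "epoch"]] = labels[idx]
            f_null, _, _ = _interaction_F(shuf)
            if f_null >= F - 1e-12:
                count += 1
        perm_p = (1 + count) / (1 + n_perm_F)

    return CoactivationStats(eff1, eff2, table, F, p, tukey, long, perm_p)


# --------------------------------------------------------------------- #
# permutation control: shuffle which SWRs contain X spikes
# --------------------------------------------------------------------- #

@dataclass
class ShuffleResult:
    observed: float
    p: float
    null: np.ndarray
    degenerate: bool = False


def swr_shuffle_control(part: ParticipationMatrix, x_unit: int, z_unit: int,
                        early_days=EARLY_DAYS, late_days=LATE_DAYS,
                        n_perm: int = 10_000, seed: int | None = None,
                        y_exclude_units: tuple[int, ...] = ()) -> ShuffleResult:
    """Early-to-late change in X-Z joint probability vs an X-shuffle null.

    Within each epoch the set of SWR indices containing X spikes is
    randomly reassigned among that epoch's SWRs (count preserved, so both
    units' firing rates are preserved) while Z participation is held
    fixed.  One-sided add-one p for an increase.
    """
    xi = part.unit_col(x_unit)
    zi = part.unit_col(z_unit)
    x_part = part.participation[:, xi]
    z_part = part.participation[:, zi].copy()
    if not x_part.any() or not z_part.any():
        raise ValidationError("both units must participate in >= 1 SWR")
    valid = np.ones(len(x_part), bool)
    if y_exclude_units:
        ycols = [part.unit_col(u) for u in y_exclude_units]
        valid = ~part.participation[:, ycols].any(axis=1)

    e_mask = part.event_mask_days(early_days)
    l_mask = part.event_mask_days(late_days)

    def stat(xp: np.ndarray) -> float:
        out = 0.0
        for m, sgn in ((l_mask, 1.0), (e_mask, -1.0)):
            N = m.sum()
            if N == 0:
                return np.nan
            out += sgn * float((xp & z_part & valid & m).sum()) / N
        return out

    observed = stat(x_part)
    rng = np.random.default_rng(seed)
    degenerate = bool(x_part[e_mask].all() and x_part[l_mask].all())
    if degenerate:
        log.warning("unit %s fires in every SWR: shuffle null is a point mass",
                    x_unit)
    null = np.empty(n_perm)
    for k in range(n_perm):
        xp = np.zeros_like(x_part)
        for m in (e_mask, l_mask):
            idx = np.flatnonzero(m)
            n_x = int(x_part[m].sum())
            xp[rng.choice(idx, size=n_x, replace=False)] = True
        null[k] = stat(xp)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_perm)
    return ShuffleResult(observed, float(p), null, degenerate)


# --------------------------------------------------------------------- #
# co-firing correlation and first-spike order
# --------------------------------------------------------------------- #

def swr_cofire_correlation(part: ParticipationMatrix,
                           pairs: list[tuple[int, int]] | None = None,
                           days=None) -> pd.DataFrame:
    """Pearson correlation of within-SWR spike counts for each unit pair."""
    counts = part.counts
    if days is not None:
        counts = counts[part.event_mask_days(days)]
    if counts.shape[0] < 10:
        log.warning("only %d SWRs: co-firing correlations are unstable",
                    counts.shape[0])
    if pairs is None:
        pairs = list(combinations(part.units, 2))
    rows = []
    for a, b in pairs:
        va = counts[:, part.unit_col(a)].astype(float)
        vb = counts[:, part.unit_col(b)].astype(float)
        if va.std() == 0 or vb.std() == 0:
            continue
        r = float(np.corrcoef(va, vb)[0, 1])
        rows.append(dict(unit_a=a, unit_b=b, r=r, n_events=len(va)))
    return pd.DataFrame(rows, columns=["unit_a", "unit_b", "r", "n_events"])


@dataclass
class FirstSpikeOrder:
    """Binomial test of which unit of each pair fires first in SWRs."""

    medians: pd.DataFrame      # pair, median dt (z - x), n events
    fraction_z_first: float    # fraction of pairs with median dt < 0
    n_pairs: int
    pvalue: float              # two-sided binomial vs 0.5
    n_dropped_ties: int


def first_spike_deltas(session: SessionData, events: pd.DataFrame,
                       x_unit: int, z_unit: int,
                       days=None) -> tuple[np.ndarray, int]:
    """Per-event first-spike time difference t_first(Z) - t_first(X).

    Restricted to SWRs where both units fire; exact ties are dropped and
    counted.
    """
    ev = events if days is None else events[events["day"].isin(list(days))]
    sx = session.spikes[x_unit]
    sz = session.spikes[z_unit]
    deltas = []
    ties = 0
    for start, end in ev[["start", "end"]].itertuples(index=False):
        ax = sx[np.searchsorted(sx, start):np.searchsorted(sx, end)]
        az = sz[np.searchsorted(sz, start):np.searchsorted(sz, end)]
        if not len(ax) or not len(az):
            continue
        d = float(az[0] - ax[0])
        if d == 0.0:
            ties += 1
            continue
        deltas.append(d)
    return np.asarray(deltas), ties


def first_spike_order(session: SessionData, events: pd.DataFrame,
                      pairs: list[tuple[int, int]],
                      days=None) -> FirstSpikeOrder:
    """Across pairs, test whether Z typically fires before X in SWRs.

    Per pair the median of the per-event differences t_first(Z) -
    t_first(X); the fraction of pairs with negative median is compared to
    0.5 with a two-sided binomial test.  When testing both cue sets, apply
    Bonferroni (alpha 0.025) at the call site.
    """
    rows = []
    total_ties = 0
    for x_unit, z_unit in pairs:
        d, ties = first_spike_deltas(session, events, x_unit, z_unit, days)
        total_ties += ties
        if d.size == 0:
            continue
        rows.append(dict(x_unit=x_unit, z_unit=z_unit,
                         median_dt=float(np.median(d)), n_events=d.size))
    med = pd.DataFrame(rows, columns=["x_unit", "z_unit", "median_dt", "n_events"])
    med = med[med["median_dt"] != 0]
    n = len(med)
    k = int((med["median_dt"] < 0).sum())
    if n == 0:
        return FirstSpikeOrder(med, np.nan, 0, 1.0, total_ties)
    p = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    if total_ties:
        log.info("dropped %d simultaneous-first-spike events", total_ties)
    return FirstSpikeOrder(med, k / n, n, p, total_ties)
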