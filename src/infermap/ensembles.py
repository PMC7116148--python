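"""Cue-ensemble identification and performance-modulation regression.

Per-neuron firing rates are computed in 100 ms bins spanning each trial,
censored at the trial's decision point, and Z-scored per unit across all
included bins.  Trial-averaged responses are regressed onto a design with
one indicator per task cue plus the standardized trial speed; a unit joins
the ensemble of cue *c* when its weight for *c* is positive and exceeds the
cross-unit mean by 2 standard deviations.

A second, time-resolved regression relates peristimulus firing to
behavioral performance (correct vs incorrect inference) with speed and cue
set as covariates, yielding one weight per 100 ms bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import decision_points
from .config import CUES
from .errors import DesignError, ValidationError
from .session import SessionData, trials_of

log = logging.getLogger(__name__)


# --------------------------------------------------------------------- #
# binning
# --------------------------------------------------------------------- #

@dataclass
class BinnedRates:
    """Unit x bin matrix of Z-scored rates with trial bookkeeping."""

    units: list[int]
    z: np.ndarray               # units x bins, Z-scored over included bins
    rates: np.ndarray           # units x bins, Hz
    bin_start: np.ndarray       # bin left edges, s
    bin_trial: np.ndarray       # trial id per bin
    included: np.ndarray        # decision-point inclusion mask per bin
    bin_s: float
    excluded_units: list[int]   # zero-variance units (flagged, z rows = 0)
    decisions: dict[int, float | None] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.z.shape[1]

    def trial_mean_z(self, trial_id: int) -> np.ndarray | None:
        m = (self.bin_trial == trial_id) & self.included
        if not m.any():
            return None
        return self.z[:, m].mean(axis=1)


def bin_and_zscore(session: SessionData, bin_s: float = 0.1,
                   decisions: dict[int, float | None] | None = None,
                   trials: pd.DataFrame | None = None) -> BinnedRates:
    """Bin spikes over trial windows, censor at decision points, Z-score.

    Bins run from each trial's onset in ``bin_s`` steps.  A bin is included
    when it ends at or before the trial's decision point; trials whose
    decision point is undefined (area entered without slowing first) are
    excluded entirely; trials without area entry are kept whole.
    """
    if trials is None:
        trials = session.trials
    if decisions is None:
        decisions = decision_points(trials, session.position)

    lefts, rights, bin_trial, included = [], [], [], []
    for _, tr in trials.iterrows():
        on, off = float(tr["onset"]), float(tr["offset"])
        n = int(math.floor((off - on) / bin_s + 1e-9))
        if n == 0:
            continue
        edges = on + bin_s * np.arange(n + 1)
        dec = decisions.get(int(tr["trial_id"]))
        if dec is None:
            inc = np.ones(n, bool)
        elif isinstance(dec, float) and math.isnan(dec):
            inc = np.zeros(n, bool)
        else:
            inc = edges[1:] <= dec + 1e-9
        lefts.append(edges[:-1])
        rights.append(edges[1:])
        bin_trial.append(np.full(n, int(tr["trial_id"])))
        included.append(inc)

    if not lefts:
        z = np.zeros((session.n_units, 0))
        return BinnedRates(session.unit_ids, z, z.copy(), np.empty(0),
                           np.empty(0, int), np.empty(0, bool), bin_s, [],
                           dict(decisions))

    lefts = np.concatenate(lefts)
    rights = np.concatenate(rights)
    bin_trial = np.concatenate(bin_trial)
    included = np.concatenate(included)

    units = session.unit_ids
    rates = np.empty((len(units), lefts.size))
    for i, u in enumerate(units):
        s = session.spikes[u]
        rates[i] = (np.searchsorted(s, rights) - np.searchsorted(s, lefts)) / bin_s

    z = np.zeros_like(rates)
    excluded: list[int] = []
    if included.any():
        mu = rates[:, included].mean(axis=1)
        sd = rates[:, included].std(axis=1)
        ok = sd > 0
        z[ok] = (rates[ok] - mu[ok, None]) / sd[ok, None]
        for i, u in enumerate(units):
            if not ok[i]:
                excluded.append(u)
                log.warning("unit %s has zero rate variance; flagged", u)
    return BinnedRates(units, z, rates, lefts, bin_trial, included, bin_s,
                       excluded, dict(decisions))


def trial_speeds(trials: pd.DataFrame, session: SessionData,
                 decisions: dict[int, float | None] | None = None) -> pd.Series:
    """Mean speed (cm/s) per trial, censored at the decision point."""
    if decisions is None:
        decisions = decision_points(trials, session.position)
    pos = session.position
    speed = pos.speed
    out = {}
    for _, tr in trials.iterrows():
        tid = int(tr["trial_id"])
        dec = decisions.get(tid)
        end = float(tr["offset"])
        if dec is not None and not (isinstance(dec, float) and math.isnan(dec)):
            end = min(end, dec)
        m = (pos.t >= tr["onset"]) & (pos.t < end)
        out[tid] = float(speed[m].mean()) if m.any() else np.nan
    return pd.Series(out, name="speed")


# --------------------------------------------------------------------- #
# cue GLM and ensemble rule
# --------------------------------------------------------------------- #

@dataclass
class CueGlmResult:
    """Per-unit regression weights for the six task cues plus speed."""

    weights: pd.DataFrame        # units x (CUES..., speed)
    r_squared: pd.Series
    n_trials: pd.Series          # trials per cue entering the fit

    def cue_weights(self, cue: str) -> pd.Series:
        return self.weights[cue]


def fit_cue_glm(binned: BinnedRates, trials: pd.DataFrame,
                speeds: pd.Series) -> CueGlmResult:
    """OLS of trial-averaged Z rate on cue indicators plus trial speed.

    Each trial presents exactly one cue, so the six indicators span the
    intercept and the fit is run without one; in a balanced design with
    constant speed the cue weight equals the per-cue mean response.
    """
    rows = []
    for _, tr in trials.iterrows():
        tid = int(tr["trial_id"])
        y = binned.trial_mean_z(tid)
        if y is None:
            continue
        rows.append((tid, tr["cue"], y, speeds.get(tid, np.nan)))
    if not rows:
        raise DesignError("no trials with included bins")

    cue_count = pd.Series([r[1] for r in rows]).value_counts()
    missing = [c for c in CUES if cue_count.get(c, 0) < 2
               and c in set(trials["cue"])]
    never = [c for c in CUES if c not in set(trials["cue"])]
    present = [c for c in CUES if c in set(trials["cue"])]
    if missing:
        raise DesignError(f"fewer than 2 usable trials for cues: {missing}")
    if not present:
        raise DesignError("no task cues present in the trial table")

    Y = np.stack([r[2] for r in rows])                    # trials x units
    cue_idx = {c: j for j, c in enumerate(present)}
    sp = np.array([r[3] for r in rows], float)
    sp = np.nan_to_num(sp, nan=float(np.nanmean(sp)) if np.isfinite(np.nanmean(sp)) else 0.0)
    sd = sp.std()
    use_speed = sd > 0            # a constant speed regressor carries nothing
    X = np.zeros((len(rows), len(present) + int(use_speed)))
    for i, r in enumerate(rows):
        X[i, cue_idx[r[1]]] = 1.0
    if use_speed:
        X[:, -1] = (sp - sp.mean()) / sd

    W, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise DesignError(f"rank-deficient cue design (missing cues: {never})")
    if not use_speed:
        W = np.vstack([W, np.zeros((1, W.shape[1]))])
    resid = Y - X @ W[: X.shape[1]]
    ss_res = (resid ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - np.divide(ss_res, ss_tot, out=np.zeros_like(ss_res),
                         where=ss_tot > 0)

    weights = pd.DataFrame(W.T, index=binned.units,
                           columns=[*present, "speed"])
    for c in never:
        weights[c] = np.nan
    weights = weights[[*CUES, "speed"]] if not never else weights
    return CueGlmResult(weights=weights,
                        r_squared=pd.Series(r2, index=binned.units),
                        n_trials=cue_count.reindex(CUES).fillna(0).astype(int))


@dataclass
class EnsembleAssignment:
    """Cue-specific ensembles from the 2-SD rule."""

    members: dict[str, list[int]]       # cue -> unit ids
    thresholds: dict[str, float]        # cue -> mean + k*SD cutoff
    k_sd: float

    def overlap(self) -> dict[int, tuple[str, ...]]:
        """Units that belong to more than one cue ensemble."""
        count: dict[int, list[str]] = {}
        for cue, us in self.members.items():
            for u in us:
                count.setdefault(u, []).append(cue)
        return {u: tuple(cs) for u, cs in count.items() if len(cs) > 1}

    def single(self, cue: str) -> list[int]:
        """Members of ``cue`` that belong to no other ensemble."""
        multi = set(self.overlap())
        return [u for u in self.members.get(cue, []) if u not in multi]

    def to_dict(self) -> dict:
        return dict(members={c: list(map(int, us)) for c, us in self.members.items()},
                    thresholds=self.thresholds, k_sd=self.k_sd)


def assign_ensembles(glm: CueGlmResult, k_sd: float = 2.0) -> EnsembleAssignment:
    """Assign each cue the units whose weight is positive and exceeds the
    cross-unit mean weight by ``k_sd`` standard deviations."""
    n_units = len(glm.weights)
    if n_units < 10:
        log.warning("only %d units: the 2-SD threshold is unstable", n_units)
    members: dict[str, list[int]] = {}
    thresholds: dict[str, float] = {}
    for cue in CUES:
        if cue not in glm.weights.columns or glm.weights[cue].isna().all():
            continue
        w = glm.weights[cue]
        thr = float(w.mean() + k_sd * w.std(ddof=1)) if n_units > 1 else np.inf
        thresholds[cue] = thr
        members[cue] = [int(u) for u in w.index[(w > thr) & (w > 0)]]
    return EnsembleAssignment(members, thresholds, k_sd)


# --------------------------------------------------------------------- #
# performance-modulation GLM
# --------------------------------------------------------------------- #

@dataclass
class PerformanceResult:
    """Time course of the correct-vs-incorrect regression weight."""

    times: np.ndarray            # bin centers relative to cue onset, s
    mean_weight: np.ndarray      # average weight across units per bin
    tstat: np.ndarray            # one-sample t across units per bin
    pvalue: np.ndarray
    unit_weights: np.ndarray     # units x bins
    n_trials: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(dict(time=self.times, weight=self.mean_weight,
                                 tstat=self.tstat, pvalue=self.pvalue))


def performance_modulation_glm(session: SessionData,
                               window_s: float = 15.0,
                               bin_s: float = 0.1) -> PerformanceResult:
    """Per-bin regression of Z rate on inference performance.

    For each 100 ms bin in a +/- ``window_s`` peristimulus window around
    auditory-cue onset, each unit's Z-scored rate across inference-test
    trials is regressed on the correct(1)/incorrect(0) flag with trial
    speed and cue set as covariates.  Days lacking both outcomes are
    dropped with a warning.
    """
    tr = trials_of(session.trials, stage="inference_test").copy()
    if not len(tr):
        raise ValidationError("no inference-test trials in session")
    keep_days = []
    for day, grp in tr.groupby("day"):
        vals = set(grp["correct"].dropna().astype(int))
        if vals == {0, 1}:
            keep_days.append(day)
        else:
            log.warning("day %s excluded: all trials %s", day,
                        "correct" if vals == {1} else "incorrect")
    tr = tr[tr["day"].isin(keep_days)]
    if not len(tr):
        raise ValidationError("no day has both correct and incorrect trials")

    n_bins = int(round(2 * window_s / bin_s))
    rel_edges = -window_s + bin_s * np.arange(n_bins + 1)
    units = session.unit_ids
    onsets = tr["onset"].values
    rates = np.empty((len(tr), len(units), n_bins))
    for i, u in enumerate(units):
        s = session.spikes[u]
        edges = onsets[:, None] + rel_edges[None, :]
        counts = np.searchsorted(s, edges)
        rates[:, i, :] = np.diff(counts, axis=1) / bin_s

    mu = rates.mean(axis=(0, 2), keepdims=True)
    sd = rates.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    z = (rates - mu) / sd

    pos = session.position
    speed = pos.speed
    sp = np.array([
        speed[(pos.t >= on - window_s) & (pos.t < on + window_s)].mean()
        if ((pos.t >= on - window_s) & (pos.t < on + window_s)).any() else 0.0
        for on in onsets
    ])
    sp = (sp - sp.mean()) / sp.std() if sp.std() > 0 else np.zeros_like(sp)
    correct = tr["correct"].astype(float).values
    set_cov = (tr["set"].values == 1).astype(float)

    X = np.column_stack([np.ones_like(correct), correct, sp, set_cov])
    # drop collinear set column if degenerate (single-set sessions)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X = X[:, :3]
    pinv = np.linalg.pinv(X)

    n_units = len(units)
    unit_w = np.empty((n_units, n_bins))
    for j in range(n_bins):
        beta = pinv @ z[:, :, j]       # coefs x units
        unit_w[:, j] = beta[1]
    tstat, pval = stats.ttest_1samp(unit_w, 0.0, axis=0)
    times = (rel_edges[:-1] + rel_edges[1:]) / 2.0
    return PerformanceResult(times=times, mean_weight=unit_w.mean(axis=0),
                             tstat=tstat, pvalue=pval, unit_weights=unit_w,
                             n_trials=len(tr))


# --------------------------------------------------------------------- #
# model / results facade
# --------------------------------------------------------------------- #

class CueEnsembleModel:
    """Cue-tuning model of a session: binned Z rates -> cue GLM -> ensembles.

    Parameters
    ----------
    session
        The recording session.
    bin_s
        Bin width in seconds (0.1 = 100 ms).
    day
        Fit one recording day, or pool all days when ``None``.
    """

    def __init__(self, session: SessionData, bin_s: float = 0.1,
                 day: int | None = None):
        self.session = session
        self.bin_s = bin_s
        self.day = day
        tr = session.trials
        self.trials = tr if day is None else tr[tr["day"] == day]

    def fit(self, k_sd: float = 2.0) -> "CueEnsembleResults":
        decisions = decision_points(self.trials, self.session.position)
        binned = bin_and_zscore(self.session, self.bin_s, decisions, self.trials)
        speeds = trial_speeds(self.trials, self.session, decisions)
        glm = fit_cue_glm(binned, self.trials, speeds)
        ens = assign_ensembles(glm, k_sd)
        return CueEnsembleResults(self, binned, glm, ens)


@dataclass
class CueEnsembleResults:
    model: CueEnsembleModel
    binned: BinnedRates
    glm: CueGlmResult
    ensembles: EnsembleAssignment

    def summary(self) -> pd.DataFrame:
        rows = []
        for cue in CUES:
            if cue not in self.ensembles.thresholds:
                continue
            rows.append(dict(
                cue=cue,
                threshold=self.ensembles.thresholds[cue],
                n_members=len(self.ensembles.members[cue]),
                members=",".join(map(str, self.ensembles.members[cue])),
            ))
        return pd.DataFrame(rows)
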