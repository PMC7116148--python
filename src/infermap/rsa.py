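"""Cross-stimulus representational similarity on population vectors.

The representational similarity matrix (RSM) here is *not* symmetric: rows
index test-stage conditions (auditory cues during the inference test) and
columns index training-stage conditions (visual or outcome cues during
conditioning).  Cells are Pearson correlations between condition pattern
vectors (one mean Z-scored rate per unit).  The learned association map
(X1->Y1, X2->Y2, ...) marks the "within" cells; the prospective-coding
statistic is mean(within) - mean(between).

Inference is run two ways, as in estimation practice for small-n designs:
a one-sided Wilcoxon signed-rank test across days/subjects, and a
permutation test in which the identities of the auditory cues are permuted
within each day before recomputing the group average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .ensembles import BinnedRates
from .errors import DesignError, ValidationError

log = logging.getLogger(__name__)


# --------------------------------------------------------------------- #
# pattern matrices
# --------------------------------------------------------------------- #

@dataclass
class PatternMatrix:
    """Feature x condition matrix of mean responses."""

    data: np.ndarray                 # features x conditions
    features: list[int]              # unit (or voxel/feature) ids
    conditions: list[str]
    n_trials: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("condition labels must be unique")

    def column(self, condition: str) -> np.ndarray:
        return self.data[:, self.conditions.index(condition)]


def population_vectors(binned: BinnedRates, trials: pd.DataFrame,
                       cues: list[str] | None = None,
                       correct: float | None = None,
                       swr_intervals: np.ndarray | None = None) -> PatternMatrix:
    """Per-condition mean Z rate per unit over included bins.

    ``correct`` restricts to trials with that performance flag (1.0 or
    0.0); ``swr_intervals`` (n x 2 seconds) excludes any bin overlapping a
    sharp-wave/ripple.  Conditions with no included bins are dropped with a
    log message, as are features that are constant across conditions.
    """
    tr = trials
    if correct is not None:
        tr = tr[tr["correct"] == correct]
    if cues is None:
        cues = [c for c in dict.fromkeys(tr["cue"])]

    bin_ok = binned.included.copy()
    if swr_intervals is not None and len(swr_intervals):
        iv = np.atleast_2d(np.asarray(swr_intervals, float))
        starts = binned.bin_start
        ends = starts + binned.bin_s
        hit = np.zeros_like(bin_ok)
        for a, b in iv:
            hit |= (starts < b) & (ends > a)
        bin_ok &= ~hit

    cols, labels, n_trials = [], [], {}
    for cue in cues:
        ids = tr[tr["cue"] == cue]["trial_id"].values
        m = np.isin(binned.bin_trial, ids) & bin_ok
        if not m.any():
            log.warning("condition %s dropped: no included bins", cue)
            continue
        cols.append(binned.z[:, m].mean(axis=1))
        labels.append(cue)
        n_trials[cue] = int(len(ids))
    if not cols:
        raise ValidationError("no conditions with included bins")

    data = np.column_stack(cols)
    keep = ~np.all(data == data[:, :1], axis=1) if data.shape[1] > 1 \
        else np.ones(data.shape[0], bool)
    dropped = [u for u, k in zip(binned.units, keep) if not k]
    if dropped:
        log.info("dropping %d constant feature rows", len(dropped))
    feats = [u for u, k in zip(binned.units, keep) if k]
    return PatternMatrix(data[keep], feats, labels, n_trials)


# --------------------------------------------------------------------- #
# RSM
# --------------------------------------------------------------------- #

@dataclass
class RSM:
    """Test x train condition matrix of Pearson correlations."""

    values: pd.DataFrame             # rows: test conditions, cols: train
    assoc: dict[str, str]            # test condition -> associated train condition

    def within_mask(self) -> pd.DataFrame:
        m = pd.DataFrame(False, index=self.values.index,
                         columns=self.values.columns)
        for t, tr in self.assoc.items():
            if t in m.index and tr in m.columns:
                m.loc[t, tr] = True
        return m

    def permuted(self, mapping: dict[str, str]) -> "RSM":
        """Relabel test conditions by ``mapping`` (a test-label permutation)."""
        new_index = [mapping.get(t, t) for t in self.values.index]
        vals = self.values.copy()
        vals.index = new_index
        return RSM(vals.loc[list(self.values.index)], self.assoc)


def cross_rsm(test: PatternMatrix, train: PatternMatrix,
              assoc: dict[str, str]) -> RSM:
    """Pearson correlation for every (test, train) condition pair."""
    shared = [f for f in test.features if f in set(train.features)]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared features; need >= 3 for correlations"
        )
    ti = [test.features.index(f) for f in shared]
    ri = [train.features.index(f) for f in shared]
    A = test.data[ti, :]
    B = train.data[ri, :]

    def _std(M: np.ndarray) -> np.ndarray:
        M = M - M.mean(axis=0, keepdims=True)
        sd = M.std(axis=0, keepdims=True)
        sd[sd == 0] = np.nan
        return M / sd

    A = _std(A)
    B = _std(B)
    r = (A.T @ B) / A.shape[0]
    vals = pd.DataFrame(r, index=test.conditions, columns=train.conditions)
    return RSM(vals, dict(assoc))


def within_minus_between(rsm: RSM, fisher: bool = False) -> float:
    """Mean correlation of associated cells minus mean of the rest."""
    v = rsm.values.values.astype(float)
    if fisher:
        v = np.arctanh(np.clip(v, -0.999999, 0.999999))
    m = rsm.within_mask().values
    if not m.any() or m.all():
        raise ValidationError("association map must mark a proper subset of cells")
    return float(v[m].mean() - v[~m].mean())


# --------------------------------------------------------------------- #
# inference
# --------------------------------------------------------------------- #

@dataclass
class PermutationResult:
    observed: float
    p: float
    null: np.ndarray
    n_perm: int


def permutation_null(stat_fn, rsms: list[RSM], n_perm: int = 10_000,
                     seed: int | None = None) -> PermutationResult:
    """One-sided permutation test of the group-mean statistic.

    On each iteration the identities of the test-stage (auditory) cue
    labels are permuted independently within each day's RSM, the statistic
    recomputed per day, and the group mean taken; add-one rule
    ``p = (1 + #{null >= obs}) / (1 + n_perm)`` avoids p = 0.
    """
    if n_perm < 100:
        log.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    rng = np.random.default_rng(seed)
    observed = float(np.mean([stat_fn(r) for r in rsms]))
    labels_per_day = [list(r.values.index) for r in rsms]
    for labels in labels_per_day:
        if len(labels) < 2:
            raise ValidationError("need >= 2 permutable test labels per day")

    few_labels = all(len(lb) <= 5 for lb in labels_per_day)
    if few_labels:
        # small label sets: pre-evaluate the statistic under every distinct
        # row permutation per day, then draw permutation indices (uniform
        # over the same permutation group, so the null is identical)
        tables = []
        for r, labels in zip(rsms, labels_per_day):
            perms = list(permutations(range(len(labels))))
            vals = []
            for perm in perms:
                mapping = {labels[i]: labels[perm[i]]
                           for i in range(len(labels))}
                vals.append(stat_fn(r.permuted(mapping)))
            tables.append(np.asarray(vals))
        picks = np.column_stack([
            rng.integers(0, len(tb), size=n_perm) for tb in tables])
        null = np.mean(np.column_stack([
            tb[picks[:, j]] for j, tb in enumerate(tables)]), axis=1)
    else:
        null = np.empty(n_perm)
        for k in range(n_perm):
            vals = []
            for r, labels in zip(rsms, labels_per_day):
                perm = rng.permutation(len(labels))
                mapping = {labels[i]: labels[perm[i]]
                           for i in range(len(labels))}
                vals.append(stat_fn(r.permuted(mapping)))
            null[k] = np.mean(vals)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_perm)
    return PermutationResult(observed, float(p), null, n_perm)


def exhaustive_permutations(labels: list[str]) -> list[dict[str, str]]:
    """All label permutations (for tiny label sets, e.g. two cues)."""
    return [dict(zip(labels, p)) for p in permutations(labels)]


def group_inference(values, alternative: str = "greater") -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test across days/subjects.

    Exact p for n <= 25 without ties (scipy's policy), normal
    approximation otherwise.  All-zero input gives p = 1 with a warning.
    """
    values = np.asarray(values, float)
    if values.size < 5:
        log.warning("only %d observations; signed-rank p is coarse", values.size)
    if np.all(values == 0):
        log.warning("all values zero; returning p = 1")
        return 0.0, 1.0
    res = stats.wilcoxon(values, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def rsm_model_regression(rsm: RSM, models: dict[str, np.ndarray],
                         fisher: bool = True) -> pd.Series:
    """Multiple regression of the vectorized RSM on model matrices.

    Cell values (optionally Fisher-transformed) are Z-scored and regressed
    on the vectorized model RSMs plus an intercept; returns one weight per
    model.  Collinear models raise with the design condition number.
    """
    y = rsm.values.values.astype(float).ravel()
    if fisher:
        y = np.arctanh(np.clip(y, -0.999999, 0.999999))
    sd = y.std()
    y = (y - y.mean()) / sd if sd > 0 else y - y.mean()

    names = list(models)
    cols = []
    for name in names:
        m = np.asarray(models[name], float)
        if m.shape != rsm.values.shape:
            raise ValidationError(
                f"model {name!r} shape {m.shape} != RSM shape {rsm.values.shape}"
            )
        cols.append(m.ravel())
    M = np.column_stack(cols)
    Mc = M - M.mean(axis=0, keepdims=True)
    cond = np.linalg.cond(Mc) if Mc.shape[1] > 1 else 1.0
    if not np.isfinite(cond) or cond > 1e8:
        raise DesignError(f"collinear model RSMs (condition number {cond:.3g})")
    X = np.column_stack([np.ones(len(y)), M])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta[1:], index=names, name="weight")


# --------------------------------------------------------------------- #
# model / results facade
# --------------------------------------------------------------------- #

class CrossStimulusRSA:
    """Cross-stage RSA over a set of days/subjects.

    Parameters
    ----------
    test_patterns, train_patterns
        One :class:`PatternMatrix` per day (index-aligned lists).
    assoc
        Learned association map from test to train conditions.
    fisher
        Fisher-transform correlations before averaging the statistic.
    """

    def __init__(self, test_patterns: list[PatternMatrix],
                 train_patterns: list[PatternMatrix],
                 assoc: dict[str, str], fisher: bool = False):
        if len(test_patterns) != len(train_patterns):
            raise ValidationError("need matching test/train pattern lists")
        self.test_patterns = test_patterns
        self.train_patterns = train_patterns
        self.assoc = dict(assoc)
        self.fisher = fisher

    def fit(self, n_perm: int = 10_000, seed: int | None = None) -> "RSAResults":
        rsms = [cross_rsm(te, trn, self.assoc)
                for te, trn in zip(self.test_patterns, self.train_patterns)]
        stat = lambda r: within_minus_between(r, fisher=self.fisher)  # noqa: E731
        per_day = np.array([stat(r) for r in rsms])
        w_stat, w_p = group_inference(per_day)
        perm = permutation_null(stat, rsms, n_perm=n_perm, seed=seed)
        return RSAResults(self, rsms, per_day, w_stat, w_p, perm)


@dataclass
class RSAResults:
    model: CrossStimulusRSA
    rsms: list[RSM]
    per_day: np.ndarray
    wilcoxon_stat: float
    wilcoxon_p: float
    permutation: PermutationResult

    @property
    def statistic(self) -> float:
        """Group-mean within-minus-between correlation."""
        return float(self.per_day.mean())

    def mean_rsm(self) -> pd.DataFrame:
        return sum(r.values for r in self.rsms) / len(self.rsms)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([dict(
            n_days=len(self.per_day),
            within_minus_between=self.statistic,
            wilcoxon_p=self.wilcoxon_p,
            permutation_p=self.permutation.p,
            n_perm=self.permutation.n_perm,
        )])
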