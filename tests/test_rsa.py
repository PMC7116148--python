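"""Cross-stimulus RSA: worked examples, oracle agreement, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import infermap as im
from infermap.rsa import (RSM, PatternMatrix, cross_rsm,
                          exhaustive_permutations, group_inference,
                          permutation_null, rsm_model_regression,
                          within_minus_between)

from oracles import rsm_bruteforce

ASSOC = {"X1": "Y1", "X2": "Y2"}


def _pm(data, conds):
    return PatternMatrix(np.asarray(data, float),
                         list(range(len(data))), conds)


def test_worked_2x2_example():
    """Patterns X1=Y1=(1,0,1,0), X2=Y2=(0,1,0,1): within=+1, between=-1,
    statistic exactly 2."""
    test = _pm([[1, 0], [0, 1], [1, 0], [0, 1]], ["X1", "X2"])
    train = _pm([[1, 0], [0, 1], [1, 0], [0, 1]], ["Y1", "Y2"])
    rsm = cross_rsm(test, train, ASSOC)
    assert rsm.values.loc["X1", "Y1"] == pytest.approx(1.0)
    assert rsm.values.loc["X1", "Y2"] == pytest.approx(-1.0)
    assert within_minus_between(rsm) == pytest.approx(2.0)


def test_identical_matrices_give_unit_diagonal(rng):
    data = rng.normal(size=(30, 4))
    test = _pm(data, ["X1", "X2", "X3", "X4"])
    train = _pm(data, ["Y1", "Y2", "Y3", "Y4"])
    rsm = cross_rsm(test, train, {"X1": "Y1"})
    np.testing.assert_allclose(np.diag(rsm.values.values), 1.0, atol=1e-12)
    assert (np.abs(rsm.values.values) <= 1.0 + 1e-12).all()


def test_cross_rsm_matches_bruteforce_oracle(rng):
    """5x5 instance agrees with per-pair scipy correlations to 1e-12."""
    test = _pm(rng.normal(size=(17, 5)), [f"X{i}" for i in range(5)])
    train = _pm(rng.normal(size=(17, 5)), [f"Y{i}" for i in range(5)])
    rsm = cross_rsm(test, train, {"X0": "Y0"})
    expected = rsm_bruteforce(test.data, train.data)
    np.testing.assert_allclose(rsm.values.values, expected, atol=1e-12)


def test_orthogonal_patterns_have_small_correlations(rng):
    test = _pm(rng.normal(size=(1000, 2)), ["X1", "X2"])
    train = _pm(rng.normal(size=(1000, 2)), ["Y1", "Y2"])
    rsm = cross_rsm(test, train, ASSOC)
    assert np.abs(rsm.values.values).max() < 0.11


def test_too_few_shared_features_raises(rng):
    test = _pm(rng.normal(size=(2, 2)), ["X1", "X2"])
    train = _pm(rng.normal(size=(2, 2)), ["Y1", "Y2"])
    with pytest.raises(im.ValidationError):
        cross_rsm(test, train, ASSOC)


def test_within_minus_between_shift_invariant(rng):
    vals = pd.DataFrame(rng.uniform(-0.5, 0.5, (2, 2)),
                        index=["X1", "X2"], columns=["Y1", "Y2"])
    r1 = RSM(vals, ASSOC)
    r2 = RSM(vals + 0.17, ASSOC)
    assert within_minus_between(r1) == pytest.approx(
        within_minus_between(r2), abs=1e-12)


def test_all_equal_cells_give_zero():
    vals = pd.DataFrame(0.3, index=["X1", "X2"], columns=["Y1", "Y2"])
    assert within_minus_between(RSM(vals, ASSOC)) == 0.0


def test_two_labels_have_two_permutations():
    assert len(exhaustive_permutations(["X1", "X2"])) == 2


def test_permutation_p_near_half_when_observed_at_null_mean(rng):
    rsms = []
    for _ in range(10):
        vals = pd.DataFrame(rng.normal(0, 0.2, (2, 2)),
                            index=["X1", "X2"], columns=["Y1", "Y2"])
        # symmetric under swap: observed equals null mean
        vals.loc["X2"] = vals.loc["X1"].values
        rsms.append(RSM(vals, ASSOC))
    res = permutation_null(within_minus_between, rsms, n_perm=2000, seed=0)
    assert 0.3 < res.p <= 1.0
    assert res.observed == pytest.approx(res.null.mean(), abs=1e-9)


def test_permutation_null_calibrated(rng):
    """Unstructured data: rejection rate at alpha=.05 in [0.03, 0.07]
    (scaled: 300 simulations, n_perm=400)."""
    rejections = 0
    n_sim = 300
    for k in range(n_sim):
        rsms = []
        for _ in range(12):
            vals = pd.DataFrame(rng.normal(0, 0.3, (2, 2)),
                                index=["X1", "X2"], columns=["Y1", "Y2"])
            rsms.append(RSM(vals, ASSOC))
        res = permutation_null(within_minus_between, rsms, n_perm=400,
                               seed=int(rng.integers(2**31)))
        rejections += res.p <= 0.05
    assert 0.03 <= rejections / n_sim <= 0.07


def test_permutation_seed_stability(rng):
    rsms = [RSM(pd.DataFrame(rng.normal(0, 0.3, (2, 2)), index=["X1", "X2"],
                             columns=["Y1", "Y2"]), ASSOC) for _ in range(8)]
    n_perm = 4000
    p1 = permutation_null(within_minus_between, rsms, n_perm, seed=1).p
    p2 = permutation_null(within_minus_between, rsms, n_perm, seed=2).p
    tol = 3 * np.sqrt(p1 * (1 - p1) / n_perm)
    assert abs(p1 - p2) <= tol + 1e-12


def test_model_regression_identifies_generating_model():
    idx = ["X1", "X2", "X3"]
    cols = ["Y1", "Y2", "Y3"]
    assoc3 = {"X1": "Y1", "X2": "Y2", "X3": "Y3"}
    a = np.eye(3)
    b = np.roll(np.eye(3), 1, axis=1)     # orthogonal to a
    rsm = RSM(pd.DataFrame(0.8 * a, index=idx, columns=cols), assoc3)
    w = rsm_model_regression(rsm, {"ident": a, "shift": b}, fisher=False)
    assert w["ident"] > 0.5
    assert abs(w["shift"]) < 1e-8
    # equal mixture of orthogonal models gives equal weights
    mix = RSM(pd.DataFrame(0.4 * a + 0.4 * b, index=idx, columns=cols),
              assoc3)
    w2 = rsm_model_regression(mix, {"a": a, "b": b}, fisher=False)
    assert w2["a"] == pytest.approx(w2["b"], abs=1e-9)


def test_model_regression_collinear_raises():
    a = np.eye(2)
    rsm = RSM(pd.DataFrame(a, index=["X1", "X2"], columns=["Y1", "Y2"]),
              ASSOC)
    with pytest.raises(im.DesignError):
        rsm_model_regression(rsm, {"a": a, "a2": 2.0 * a}, fisher=False)


def test_group_inference_all_positive_minimal_p():
    n = 12
    stat, p = group_inference(np.linspace(0.1, 1.0, n))
    assert p == pytest.approx(0.5 ** n, rel=1e-6)


def test_group_inference_all_zero_flagged():
    _, p = group_inference(np.zeros(8))
    assert p == 1.0


def test_group_inference_power_at_one_sigma_shift(rng):
    """n=18 shifted normals (delta = 1 sigma): power > 0.9 (scaled to 200
    replicates)."""
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        _, p = group_inference(rng.normal(1.0, 1.0, 18))
        hits += p < 0.05
    assert hits / n_rep > 0.9


def test_group_calibration_symmetric_null(rng):
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        _, p = group_inference(rng.normal(0.0, 1.0, 18))
        hits += p < 0.05
    assert 0.02 <= hits / n_rep <= 0.08


def test_planted_association_power(small_session):
    """Planted X->Y lag similarity drives the group statistic positive
    with Wilcoxon and permutation support across simulated days."""
    tests, trains = [], []
    for seed in range(3):
        cfg = im.make_demo_config(seed, n_days=3)
        s, truth = im.generate_session(cfg)
        for day in s.days:
            from infermap.pipeline import day_patterns
            try:
                te, trn = day_patterns(s, day, 1.0,
                                       truth.swr[["start", "end"]].values)
            except im.InfermapError:
                continue
            if set(te.conditions) >= {"X1", "X2"}:
                tests.append(te)
                trains.append(trn)
    res = im.CrossStimulusRSA(tests, trains, ASSOC).fit(n_perm=1000, seed=0)
    assert res.statistic > 0
    assert res.wilcoxon_p < 0.05
    assert res.permutation.p < 0.05
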