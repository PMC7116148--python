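"""Ripple detection, coactivation probabilities, permutation controls."""

import numpy as np
import pandas as pd
import pytest

import infermap as im
from infermap.session import LfpTrace
from infermap.swr import (EARLY_DAYS, LATE_DAYS, ParticipationMatrix, SwrSet,
                          coactivation_anova, coactivation_probability,
                          detect_swrs, first_spike_order, participation_matrix,
                          swr_cofire_correlation, swr_shuffle_control,
                          CoactivationResult)

from oracles import coactivation_bruteforce


def _events(n_early, n_late):
    rows = []
    t = 0.0
    for k in range(n_early + n_late):
        rows.append(dict(start=t, end=t + 0.06,
                         day=1 if k < n_early else 5,
                         context="awake_rest", source="ground_truth"))
        t += 1.0
    return pd.DataFrame(rows)


def _part(counts, events):
    counts = np.asarray(counts)
    return ParticipationMatrix(counts, list(range(counts.shape[1])), events)


# ------------------------------------------------------------------ #
# detection
# ------------------------------------------------------------------ #

def test_identical_channels_cancel(rng):
    x = rng.standard_normal(60_000).astype(np.float32)
    lfp = LfpTrace(1000.0, 0.0, x, x.copy())
    t = np.arange(0, 60, 0.04)
    sw = detect_swrs(lfp, t, np.zeros_like(t))
    assert len(sw) == 0


def test_detection_amplitude_scale_invariant(small_cfg, small_session):
    s, truth = small_session
    lfp = im.generate_lfp(small_cfg, truth,
                          t_end=float(s.epochs["end"].max()))
    sw1 = detect_swrs(lfp, s.position.t, s.position.speed)
    lfp2 = LfpTrace(lfp.fs, lfp.t0, lfp.data * 37.0, lfp.ref * 37.0)
    sw2 = detect_swrs(lfp2, s.position.t, s.position.speed)
    pd.testing.assert_frame_equal(sw1.events[["start", "end"]],
                                  sw2.events[["start", "end"]])


def test_detection_requires_adequate_rate(rng):
    lfp = LfpTrace(300.0, 0.0, rng.standard_normal(3000),
                   rng.standard_normal(3000))
    with pytest.raises(im.ValidationError):
        detect_swrs(lfp, np.arange(10.0), np.zeros(10))


def test_no_detection_during_movement(small_cfg, small_session):
    s, truth = small_session
    lfp = im.generate_lfp(small_cfg, truth,
                          t_end=float(s.epochs["end"].max()))
    sw = detect_swrs(lfp, s.position.t, s.position.speed)
    speed = s.position.speed
    for start, end in sw.intervals():
        m = (s.position.t >= start) & (s.position.t <= end)
        if m.any():
            assert speed[m].min() < 1.5


# ------------------------------------------------------------------ #
# p_hat formula
# ------------------------------------------------------------------ #

def test_phat_formula_arithmetic():
    """n=5 of N=50, f=2 Hz -> p_hat = 0.05 exactly."""
    ev = _events(50, 50)
    counts = np.zeros((100, 3), int)
    counts[:5, :] = 1                  # coactive in 5 early events
    counts[50:60, :] = 1               # and 10 late events
    part = _part(counts, ev)
    r = coactivation_probability(part, (0, 1, 2),
                                 {u: 2.0 for u in range(3)},
                                 {u: 2.0 for u in range(3)})
    assert r.p_early == (5 / 50) / 2.0 == 0.05
    assert r.p_late == (10 / 50) / 2.0
    assert r.p_diff == pytest.approx(0.05)


def test_phat_equal_rates_everywhere_gives_zero_diff():
    ev = _events(40, 40)
    counts = np.ones((80, 3), int)
    part = _part(counts, ev)
    r = coactivation_probability(part, (0, 1, 2),
                                 {u: 3.0 for u in range(3)},
                                 {u: 3.0 for u in range(3)})
    assert r.p_diff == 0.0


def test_phat_matches_event_counting_oracle(rng):
    """Exact agreement with the brute-force oracle on random sessions."""
    for _ in range(10):
        n_e, n_l = int(rng.integers(20, 80)), int(rng.integers(20, 80))
        ev = _events(n_e, n_l)
        counts = rng.poisson(0.5, size=(n_e + n_l, 5))
        part = _part(counts, ev)
        r_e = {u: float(rng.uniform(0.5, 4.0)) for u in range(5)}
        r_l = {u: float(rng.uniform(0.5, 4.0)) for u in range(5)}
        res = coactivation_probability(part, (0, 2, 4), r_e, r_l,
                                       exclude_units=(1,))
        ev_spikes = [{u: counts[i, u] for u in range(5)}
                     for i in range(n_e + n_l)]
        p_e, p_l = coactivation_bruteforce(ev_spikes, (0, 2, 4), n_e,
                                           r_e, r_l, exclude_units=(1,))
        if res is None:
            assert p_e == 0 and p_l == 0
        else:
            assert res.p_early == p_e
            assert res.p_late == p_l


def test_doublet_absence_of_y_monotone(rng):
    """Conditioning on Y silence can only reduce the joint count."""
    ev = _events(60, 60)
    counts = rng.poisson(0.7, size=(120, 3))
    part = _part(counts, ev)
    rates = {u: 1.0 for u in range(3)}
    any_y = coactivation_probability(part, (0, 2), rates, rates)
    no_y = coactivation_probability(part, (0, 2), rates, rates,
                                    exclude_units=(1,))
    if any_y is not None and no_y is not None:
        assert no_y.n_early <= any_y.n_early
        assert no_y.n_late <= any_y.n_late


def test_anova_planted_interaction_and_null(rng):
    def make_results(diff):
        out = []
        for _ in range(40):
            pe = max(rng.normal(0.05, 0.01), 1e-3)
            pl = max(rng.normal(0.05 + diff, 0.01), 1e-3)
            out.append(CoactivationResult((0, 1, 2), "", 1, 10, 1.0, pe,
                                          1, 10, 1.0, pl))
        return out

    stats_ = coactivation_anova(make_results(0.04), make_results(0.0),
                                n_boot=1000, seed=0)
    assert stats_.interaction_p < 0.001
    assert stats_.effect_set1.ci_low > 0
    null = coactivation_anova(make_results(0.0), make_results(0.0),
                              n_boot=1000, seed=1)
    assert null.interaction_p > 0.001


def test_anova_additive_shift_no_interaction(rng):
    """A common early->late shift in both sets is a main effect, not an
    interaction."""
    def make(shift):
        return [CoactivationResult((0, 1, 2), "", 1, 10, 1.0,
                                   max(rng.normal(0.05, 0.01), 1e-3),
                                   1, 10, 1.0,
                                   max(rng.normal(0.05 + shift, 0.01), 1e-3))
                for _ in range(30)]
    st = coactivation_anova(make(0.05), make(0.05), n_boot=500, seed=2)
    assert st.interaction_p > 0.01
    assert st.anova.loc["C(epoch)", "PR(>F)"] < 1e-6


def test_anova_empty_cell_raises():
    with pytest.raises(im.ValidationError):
        coactivation_anova([], [CoactivationResult((0,), "", 1, 10, 1.0, 0.1,
                                                   1, 10, 1.0, 0.1)] * 3,
                           n_boot=1000)


# ------------------------------------------------------------------ #
# shuffle control
# ------------------------------------------------------------------ #

def test_shuffle_preserves_participation_counts(rng):
    ev = _events(30, 30)
    counts = rng.poisson(0.4, size=(60, 2))
    counts[0, 0] = counts[0, 1] = 1
    part = _part(counts, ev)
    res = swr_shuffle_control(part, 0, 1, n_perm=200, seed=0)
    assert len(res.null) == 200
    # identical participation puts the observed statistic at the extreme
    part_same = _part(np.column_stack([counts[:, 0], counts[:, 0]]), ev)
    res_same = swr_shuffle_control(part_same, 0, 1, n_perm=500, seed=0)
    assert 0.0 < res_same.p <= 1.0


def test_shuffle_calibrated_under_independence(rng):
    """Independent X and Z participation: p roughly uniform (scaled:
    100 sims, 200 permutations)."""
    hits = 0
    n_sim = 100
    for _ in range(n_sim):
        ev = _events(40, 40)
        counts = np.column_stack([rng.random(80) < 0.3,
                                  rng.random(80) < 0.3]).astype(int)
        if not (counts[:, 0].any() and counts[:, 1].any()):
            continue
        res = swr_shuffle_control(_part(counts, ev), 0, 1, n_perm=200,
                                  seed=int(rng.integers(2**31)))
        hits += res.p <= 0.05
    assert hits / n_sim <= 0.09


def test_maximal_dependence_extreme_tail(rng):
    ev = _events(40, 40)
    x = (rng.random(80) < 0.1).astype(int)
    x[:40] = 0                       # fires only late: strong increase
    x[40:50] = 1
    part = _part(np.column_stack([x, x]), ev)
    res = swr_shuffle_control(part, 0, 1, n_perm=1000, seed=3)
    assert res.p < 0.01


# ------------------------------------------------------------------ #
# co-firing correlation and first-spike order
# ------------------------------------------------------------------ #

def test_cofire_identical_counts_r1(rng):
    ev = _events(20, 20)
    c = rng.poisson(1.0, size=(40, 1))
    part = _part(np.column_stack([c, c]), ev)
    df = swr_cofire_correlation(part)
    assert df["r"].iloc[0] == pytest.approx(1.0)


def test_cofire_independent_near_zero(rng):
    ev = _events(250, 250)
    part = _part(rng.poisson(1.0, size=(500, 40)), ev)
    df = swr_cofire_correlation(part)
    assert abs(df["r"].mean()) < 0.02


def test_cofire_planted_coparticipation_positive(rng):
    ev = _events(100, 100)
    shared = (rng.random(200) < 0.8).astype(int)
    a = shared * rng.poisson(2.0, 200)
    b = shared * rng.poisson(2.0, 200)
    part = _part(np.column_stack([a, b]), ev)
    df = swr_cofire_correlation(part)
    # shared participation gate drives r well above the ~0.14 null 2SE
    assert df["r"].iloc[0] > 0.15


def _session_for_first_spike(deltas, starts):
    """Two units with one spike per event; unit 1 leads unit 0 by delta."""
    spikes = {0: np.sort(starts + 0.030),
              1: np.sort(starts + 0.030 + deltas)}
    trials = pd.DataFrame(columns=im.session.TRIAL_COLUMNS)
    pos = im.PositionTrace(np.array([0.0, 1.0]), np.zeros(2), np.zeros(2),
                           [(0, 0), (1, 0), (1, 1), (0, 1)])
    return im.SessionData(spikes=spikes, trials=trials, position=pos,
                          epochs=pd.DataFrame(columns=["day", "context",
                                                       "start", "end"]))


def test_first_spike_planted_order():
    starts = np.arange(50) * 1.0
    ev = pd.DataFrame(dict(start=starts, end=starts + 0.08, day=1,
                           context="awake_rest", source="ground_truth"))
    s = _session_for_first_spike(np.full(50, -0.005), starts)
    res = first_spike_order(s, ev, [(0, 1)], days=(1,))
    assert res.fraction_z_first == 1.0
    assert res.medians["median_dt"].iloc[0] == pytest.approx(-0.005)


def test_first_spike_time_reversal_flips_sign():
    rng = np.random.default_rng(8)
    starts = np.arange(30) * 1.0
    deltas = rng.uniform(-0.02, 0.02, 30)
    ev = pd.DataFrame(dict(start=starts, end=starts + 0.08, day=1,
                           context="awake_rest", source="ground_truth"))
    s = _session_for_first_spike(deltas, starts)
    from infermap.swr import first_spike_deltas
    d, _ = first_spike_deltas(s, ev, 0, 1)
    T = 100.0
    s_rev = im.SessionData(
        spikes={0: np.sort(T - s.spikes[0]), 1: np.sort(T - s.spikes[1])},
        trials=s.trials, position=s.position, epochs=s.epochs)
    ev_rev = pd.DataFrame(dict(start=np.sort(T - ev["end"].values),
                               end=np.sort(T - ev["start"].values),
                               day=1, context="awake_rest",
                               source="ground_truth"))
    d_rev, _ = first_spike_deltas(s_rev, ev_rev, 0, 1)
    np.testing.assert_allclose(np.sort(d_rev), np.sort(-d), atol=1e-12)


def test_first_spike_calibrated_under_independence(rng):
    """Independent spike timing: binomial rejection near alpha (scaled:
    150 sims of 24 pairs x 30 events)."""
    hits = 0
    n_sim = 150
    starts = np.arange(30) * 1.0
    ev = pd.DataFrame(dict(start=starts, end=starts + 0.08, day=1,
                           context="awake_rest", source="ground_truth"))
    for _ in range(n_sim):
        spikes = {}
        pairs = []
        for k in range(24):
            spikes[2 * k] = np.sort(starts + rng.uniform(0, 0.08, 30))
            spikes[2 * k + 1] = np.sort(starts + rng.uniform(0, 0.08, 30))
            pairs.append((2 * k, 2 * k + 1))
        s = im.SessionData(spikes=spikes,
                           trials=pd.DataFrame(columns=im.session.TRIAL_COLUMNS),
                           position=im.PositionTrace(
                               np.array([0.0, 1.0]), np.zeros(2), np.zeros(2),
                               [(0, 0), (1, 0), (1, 1), (0, 1)]),
                           epochs=pd.DataFrame(columns=["day", "context",
                                                        "start", "end"]))
        res = first_spike_order(s, ev, pairs)
        hits += res.pvalue < 0.05
    assert hits / n_sim <= 0.09


# ------------------------------------------------------------------ #
# generator integration
# ------------------------------------------------------------------ #

def test_planted_coactivation_schedule_recovered(demo_session):
    """Set-1 triplets rise early->late; set-2 stays flat (Fig-7C-like
    pattern on the demo session, using ground-truth events)."""
    cfg, s, truth = demo_session
    part = participation_matrix(s, SwrSet.from_truth(truth.swr),
                                context="awake_rest")
    from infermap.swr import epoch_rates
    r_e = epoch_rates(s, EARLY_DAYS)
    r_l = epoch_rates(s, LATE_DAYS)
    set1 = cfg.coactivation_sets[0].units
    set2 = cfg.coactivation_sets[1].units
    res1 = coactivation_probability(part, set1[:3], r_e, r_l)
    res2 = coactivation_probability(part, set2[:3], r_e, r_l)
    assert res1 is not None and res1.p_diff > 0
    assert res2 is None or abs(res2.p_diff) < res1.p_diff
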