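"""Generator ground truth, determinism and statistical invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import infermap as im
from infermap.config import IMMOBILITY_SPEED


def test_same_seed_gives_identical_sessions():
    cfg = im.make_demo_config(7, n_days=1)
    s1, t1 = im.generate_session(cfg)
    s2, t2 = im.generate_session(im.make_demo_config(7, n_days=1))
    for u in s1.unit_ids:
        np.testing.assert_array_equal(s1.spikes[u], s2.spikes[u])
    pd.testing.assert_frame_equal(s1.trials, s2.trials)
    np.testing.assert_array_equal(s1.position.x, s2.position.x)
    pd.testing.assert_frame_equal(t1.swr, t2.swr)


def test_different_seeds_differ():
    s1, _ = im.generate_session(im.make_demo_config(1, n_days=1))
    s2, _ = im.generate_session(im.make_demo_config(2, n_days=1))
    assert any(len(s1.spikes[u]) != len(s2.spikes[u]) or
               not np.array_equal(s1.spikes[u], s2.spikes[u])
               for u in s1.unit_ids)


@pytest.mark.parametrize("field,value", [
    ("n_units", 0),
    ("tuned_fraction", 1.5),
    ("tuning_gain", -1.0),
    ("swr_band", (250.0, 135.0)),
    ("swr_duration", 0.0),
    ("lfp_snr", -2.0),
    ("baseline_rate", -1.0),
])
def test_invalid_config_names_field(field, value):
    cfg = im.SynthConfig()
    setattr(cfg, field, value)
    with pytest.raises(im.ValidationError) as e:
        cfg.validate()
    assert field.split("_")[0] in str(e.value) or field in str(e.value)


def test_untuned_unit_rate_matches_baseline():
    """Empirical rate of untuned units within 3 SE of baseline (no
    speed coupling, no tuning)."""
    cfg = im.SynthConfig(n_units=10, n_days=1, tuning_gain=0.0,
                         speed_coupling=0.0, baseline_rate=2.0,
                         trials_per_day={"observational": 0,
                                         "conditioning": 10,
                                         "inference_test": 10},
                         seed=11)
    s, _ = im.generate_session(cfg)
    T = float(s.epochs["end"].max())
    for u in s.unit_ids:
        n = len(s.spikes[u])
        se = np.sqrt(2.0 * T)        # Poisson SE of the count
        assert abs(n - 2.0 * T) < 3 * se


def test_no_signal_means_no_ensembles_above_chance():
    """With zero gain and no coactivation, the 2-SD rule assigns only at
    the chance level implied by the threshold."""
    cfg = im.SynthConfig(n_units=40, n_days=1, tuning_gain=0.0,
                         speed_coupling=0.0,
                         trials_per_day={"observational": 0,
                                         "conditioning": 30,
                                         "inference_test": 30},
                         iti_s=1.0, post_cue_window=2.0,
                         rest_block_s=10.0, seed=5)
    s, _ = im.generate_session(cfg)
    res = im.CueEnsembleModel(s).fit()
    n_assigned = sum(len(v) for v in res.ensembles.members.values())
    # mean + 2 SD keeps roughly the upper ~2% tail per cue by construction
    assert n_assigned <= 0.08 * 40 * 6


def test_speed_trace_continuous_and_nonnegative(small_session):
    s, _ = small_session
    speed = s.position.speed
    assert (speed >= 0).all()
    step = np.hypot(np.diff(s.position.x), np.diff(s.position.y))
    assert step.max() < 16.0 / 25.0 * 1.5   # max speed * dt with slack


def test_swrs_lie_in_immobility(small_session):
    s, truth = small_session
    speed = s.position.speed
    t = s.position.t
    for start, end in truth.swr[["start", "end"]].itertuples(index=False):
        m = (t >= start - 0.1) & (t <= end + 0.1)
        assert speed[m].max() < IMMOBILITY_SPEED


def test_swr_participants_subset_of_configured(small_cfg, small_session):
    _, truth = small_session
    allowed = set()
    for cset in small_cfg.coactivation_sets:
        allowed |= set(cset.units)
    for p in truth.swr_participants:
        assert set(p) <= allowed


def test_triplet_participation_matches_probability():
    """Fraction of late-day SWRs containing the planted set within the
    binomial 99% CI of the configured probability."""
    cfg = im.SynthConfig(n_units=9, n_days=2, baseline_rate=0.2,
                         tuned_fraction=0.0, speed_coupling=0.0,
                         trials_per_day={"observational": 0,
                                         "conditioning": 2,
                                         "inference_test": 2},
                         rest_block_s=400.0, swr_rate=0.4, seed=21)
    cfg.coactivation_sets = [im.CoactivationSet(units=(0, 1, 2),
                                                p_early=0.3, p_late=0.3)]
    s, truth = im.generate_session(cfg)
    part = im.participation_matrix(s, im.SwrSet.from_truth(truth.swr))
    joint = part.participation[:, [0, 1, 2]].all(axis=1)
    n, k = len(joint), int(joint.sum())
    lo, hi = stats.binom.interval(0.99, n, 0.3)
    # small upward allowance for natural (non-injected) coincidences
    assert lo <= k <= hi + 0.01 * n + 3


def test_planted_decision_points_recovered(small_session):
    s, truth = small_session
    dps = im.decision_points(s.trials, s.position)
    planted = {k: v for k, v in truth.decision_points.items() if v is not None}
    assert len(planted) > 10
    for tid, d_true in planted.items():
        d_est = dps[tid]
        assert d_est is not None and not np.isnan(d_est)
        assert abs(d_est - d_true) <= 1.0 / 25.0 + 1e-9


def test_lfp_burst_power_exceeds_background(small_cfg, small_session):
    s, truth = small_session
    lfp = im.generate_lfp(small_cfg, truth, t_end=float(s.epochs["end"].max()))
    sw = im.detect_swrs(lfp, s.position.t, s.position.speed, epochs=s.epochs)
    assert len(sw) > 0
    assert (sw.events["peak_sd"] > 7.0).all()


def test_lfp_requires_positive_snr(small_cfg, small_session):
    _, truth = small_session
    cfg = im.make_demo_config(0, n_days=2)
    cfg.lfp_snr = 0.0
    with pytest.raises(im.ValidationError):
        im.generate_lfp(cfg, truth)
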