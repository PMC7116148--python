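"""End-to-end pipeline: simulate -> behavior -> ensembles -> rsa -> timing -> swr.

Each stage is a plain function on a session (so the CLI and the library
share one code path); :func:`run_pipeline` chains them, writes JSON
results plus a plain-text report, and records every threshold and seed
used.  The demo configuration plants the qualitative effects the analyses
are built to find: set-1-only ripple coactivation growth with
reversed-order (Z before X) injected spikes, within-set millisecond lags
during inference, and lag-driven X->Y pattern similarity on correct
trials.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import bootstrap_effect_size, reward_seeking_bias
from .config import ASSOC_XY, CoactivationSet, SynthConfig
from .ensembles import (CueEnsembleModel, bin_and_zscore,
                        performance_modulation_glm)
from .errors import InfermapError
from .rsa import CrossStimulusRSA, population_vectors
from .session import SessionData, trials_of
from .spiketiming import spike_triggered_average, sta_asymmetry
from .swr import (SwrSet, coactivation_anova, detect_swrs, epoch_rates,
                  first_spike_order, participation_matrix, swr_shuffle_control,
                  triplet_coactivation)
from .synth import GroundTruth, generate_lfp, generate_session, planted_tuning

log = logging.getLogger(__name__)


def make_demo_config(seed: int = 0, **overrides) -> SynthConfig:
    """Desk-scale 8-day demo session with all planted effects."""
    cfg = SynthConfig(
        n_units=30, n_days=8,
        trials_per_day={"observational": 0, "conditioning": 8,
                        "inference_test": 10},
        baseline_range=(0.5, 3.0),
        rest_block_s=60.0, awake_rest_s=40.0, iti_s=2.0,
        post_cue_window=10.0, test_block_size=3,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    tuning = planted_tuning(cfg)
    by_cue = {c: sorted(u for u, cc in tuning.items() if cc == c)
              for c in ("X1", "Y1", "Z1", "X2", "Y2", "Z2")}
    s1 = tuple(by_cue["X1"] + by_cue["Y1"] + by_cue["Z1"])
    s2 = tuple(by_cue["X2"] + by_cue["Y2"] + by_cue["Z2"])
    # set 1 grows its ripple coactivation from early to late days and its
    # injected spikes run outcome-before-cue (Z then X); set 2 stays flat
    cfg.coactivation_sets = [
        CoactivationSet(units=s1, p_early=0.02, p_late=0.10,
                        order=tuple(by_cue["Z1"] + by_cue["X1"]),
                        order_lag_ms=3.0, label="set1"),
        CoactivationSet(units=s2, p_early=0.02, p_late=0.02, label="set2"),
    ]
    cfg.planted_lag_ms = {
        (by_cue["X1"][i], by_cue["Y1"][i]): 15.0
        for i in range(min(len(by_cue["X1"]), len(by_cue["Y1"])))
    }
    cfg.planted_lag_ms.update({
        (by_cue["X2"][i], by_cue["Y2"][i]): 15.0
        for i in range(min(len(by_cue["X2"]), len(by_cue["Y2"])))
    })
    return cfg


# --------------------------------------------------------------------- #
# stages
# --------------------------------------------------------------------- #

def stage_behavior(session: SessionData, n_boot: int = 10_000,
                   seed: int | None = None) -> dict:
    out: dict = {}
    for measure in ("conditioning_cue_window", "inference_window_20s"):
        bias = reward_seeking_bias(session.trials, session.position,
                                   measure=measure, licks=session.licks,
                                   post_window=session.meta.get(
                                       "post_cue_window", 20.0))
        entry: dict = {"per_day": bias.to_dict(orient="list")}
        if len(bias) >= 2:
            eff = bootstrap_effect_size(bias["set1"].values, bias["set2"].values,
                                        n_boot=n_boot, seed=seed, paired=True)
            entry["effect"] = eff.to_dict()
        out[measure] = entry
    return out


def stage_ensembles(session: SessionData, k_sd: float = 2.0) -> dict:
    res = CueEnsembleModel(session).fit(k_sd=k_sd)
    out = dict(ensembles=res.ensembles.to_dict(),
               n_overlapping=len(res.ensembles.overlap()))
    try:
        perf = performance_modulation_glm(session)
        in_cue = (perf.times >= 0) & (perf.times < 10.0)
        out["performance_glm"] = dict(
            mean_weight_in_cue=float(perf.mean_weight[in_cue].mean()),
            mean_weight_pre_cue=float(perf.mean_weight[~in_cue & (perf.times < 0)].mean()),
            min_p_in_cue=float(perf.pvalue[in_cue].min()),
            n_trials=perf.n_trials,
        )
    except InfermapError as e:
        out["performance_glm"] = dict(skipped=str(e))
    return res, out


def day_patterns(session: SessionData, day: int, correct: float | None,
                 swr_intervals=None):
    """Test (auditory, inference) and train (visual, conditioning)
    pattern matrices for one day."""
    tr = session.trials[session.trials["day"] == day]
    binned = bin_and_zscore(session, trials=tr)
    test = population_vectors(binned, trials_of(tr, stage="inference_test"),
                              cues=["X1", "X2"], correct=correct,
                              swr_intervals=swr_intervals)
    train = population_vectors(binned, trials_of(tr, stage="conditioning"),
                               cues=["Y1", "Y2"], swr_intervals=swr_intervals)
    return test, train


def stage_rsa(session: SessionData, n_perm: int = 1000,
              seed: int | None = None, swr_intervals=None) -> dict:
    out = {}
    for label, correct in (("correct", 1.0), ("incorrect", 0.0)):
        tests, trains = [], []
        for day in session.days:
            try:
                te, trn = day_patterns(session, day, correct, swr_intervals)
            except InfermapError:
                continue
            if set(te.conditions) >= {"X1", "X2"} and \
                    set(trn.conditions) >= {"Y1", "Y2"}:
                tests.append(te)
                trains.append(trn)
        if not tests:
            out[label] = dict(skipped="no usable days")
            continue
        res = CrossStimulusRSA(tests, trains, ASSOC_XY).fit(
            n_perm=n_perm, seed=seed)
        out[label] = dict(
            n_days=len(tests),
            within_minus_between=res.statistic,
            wilcoxon_p=res.wilcoxon_p,
            permutation_p=res.permutation.p,
        )
    return out


def stage_timing(session: SessionData, pairs_within, pairs_cross,
                 n_boot: int = 10_000, seed: int | None = None) -> dict:
    tr = trials_of(session.trials, stage="inference_test")
    windows = np.column_stack([tr["onset"].values, tr["offset"].values])
    out = {}
    for label, pairs in (("within_set", pairs_within), ("cross_set", pairs_cross)):
        stas = [spike_triggered_average(session.spikes[a], session.spikes[b],
                                        windows, pair=(a, b))
                for a, b in pairs]
        included = [s for s in stas if s.included]
        if len(included) < 2:
            out[label] = dict(skipped=f"{len(included)} included pairs")
            continue
        vals, eff = sta_asymmetry(stas, n_boot=n_boot, seed=seed)
        out[label] = dict(n_pairs=len(vals), effect=eff.to_dict())
    return out


def stage_swr(session: SessionData, truth: GroundTruth | None,
              ensembles, n_boot: int = 10_000, n_perm: int = 1000,
              seed: int | None = None, context: str = "awake_rest",
              max_tuples: int | None = 200) -> dict:
    if session.lfp is not None:
        swrs = detect_swrs(session.lfp, session.position.t,
                           session.position.speed, epochs=session.epochs)
    elif truth is not None:
        swrs = SwrSet.from_truth(truth.swr)
    else:
        return dict(skipped="no LFP and no ground-truth events")
    part = participation_matrix(session, swrs, context=context)
    if not len(part.events):
        return dict(skipped=f"no SWRs in context {context!r}")
    r_early = epoch_rates(session, (1, 2, 3, 4))
    r_late = epoch_rates(session, (5, 6, 7, 8))

    out = dict(n_events=int(len(part.events)))
    trip1 = triplet_coactivation(part, ensembles, ("X1", "Y1", "Z1"),
                                 r_early, r_late, max_tuples=max_tuples)
    trip2 = triplet_coactivation(part, ensembles, ("X2", "Y2", "Z2"),
                                 r_early, r_late, max_tuples=max_tuples)
    if len(trip1) >= 2 and len(trip2) >= 2:
        stats_ = coactivation_anova(trip1, trip2, n_boot=n_boot, seed=seed)
        out["triplets"] = dict(
            n_set1=len(trip1), n_set2=len(trip2),
            set1_p_diff=stats_.effect_set1.to_dict(),
            set2_p_diff=stats_.effect_set2.to_dict(),
            interaction_F=stats_.interaction_F,
            interaction_p=stats_.interaction_p,
        )
    else:
        out["triplets"] = dict(skipped="too few coactive triplets")

    x1 = ensembles.single("X1")
    z1 = ensembles.single("Z1")
    if x1 and z1:
        try:
            sh = swr_shuffle_control(part, x1[0], z1[0], n_perm=n_perm,
                                     seed=seed)
            out["shuffle_control_X1Z1"] = dict(observed=sh.observed, p=sh.p)
        except InfermapError as e:
            out["shuffle_control_X1Z1"] = dict(skipped=str(e))
    pairs1 = [(x, z) for x in x1 for z in z1]
    fs = first_spike_order(session, part.events, pairs1)
    out["first_spike_set1"] = dict(fraction_z_first=fs.fraction_z_first,
                                   n_pairs=fs.n_pairs, p=fs.pvalue)
    x2, z2 = ensembles.single("X2"), ensembles.single("Z2")
    fs2 = first_spike_order(session, part.events,
                            [(x, z) for x in x2 for z in z2])
    out["first_spike_set2"] = dict(fraction_z_first=fs2.fraction_z_first,
                                   n_pairs=fs2.n_pairs, p=fs2.pvalue)
    return out


# --------------------------------------------------------------------- #
# orchestration
# --------------------------------------------------------------------- #

def _round_floats(obj, nd: int = 9):
    if isinstance(obj, float):
        if obj != obj:
            return None
        return 0.0 if obj == 0 else round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), nd)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is None or isinstance(obj, (str, int, bool)):
        return obj
    if isinstance(obj, float) and (obj != obj):
        return None
    return obj


def report_hash(report: dict) -> str:
    """Stable hash of a report up to 1e-9 float tolerance."""
    payload = json.dumps(_round_floats(report), sort_keys=True,
                         allow_nan=True)
    return hashlib.sha256(payload.encode("utf8")).hexdigest()


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the full demo pipeline; returns (and optionally writes) a report.

    ``config`` keys: ``seed`` (int), ``stages`` (list of stage names),
    ``n_perm``, ``n_boot``, ``with_lfp`` (bool; detect ripples from a
    synthesized LFP instead of using ground-truth events), plus any
    :class:`SynthConfig` field overrides under ``synth``.
    """
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_perm", 1000))
    n_boot = int(config.get("n_boot", 2000))
    stages = config.get("stages",
                        ["behavior", "ensembles", "rsa", "timing", "swr"])
    cfg = make_demo_config(seed, **config.get("synth", {}))

    report: dict = dict(parameters=dict(
        seed=seed, n_perm=n_perm, n_boot=n_boot,
        bin_s=0.1, ensemble_k_sd=2.0, decision_speed_cms=5.0,
        immobility_speed_cms=1.5, swr_threshold_sd=7.0, swr_edge_sd=2.0,
        swr_band_hz=list(cfg.swr_band), synth=cfg.to_dict(), stages=stages,
    ))

    session, truth = generate_session(cfg)
    if config.get("with_lfp"):
        session.lfp = generate_lfp(cfg, truth, t_end=float(
            session.epochs["end"].max()))

    ens_res = None
    for stage in stages:
        try:
            if stage == "behavior":
                report["behavior"] = stage_behavior(session, n_boot, seed)
            elif stage == "ensembles":
                ens_res, out = stage_ensembles(session)
                report["ensembles"] = out
            elif stage == "rsa":
                report["rsa"] = stage_rsa(session, n_perm, seed,
                                          swr_intervals=truth.swr[
                                              ["start", "end"]].values)
            elif stage == "timing":
                within = list(truth.pair_lags)
                by_cue = {c: truth.tuned_units(c) for c in
                          ("X1", "X2", "Y1", "Y2")}
                cross = [(x, y) for x in by_cue["X1"] for y in by_cue["Y2"]]
                cross += [(x, y) for x in by_cue["X2"] for y in by_cue["Y1"]]
                report["timing"] = stage_timing(session, within, cross,
                                                n_boot, seed)
            elif stage == "swr":
                if ens_res is None:
                    ens_res = CueEnsembleModel(session).fit()
                report["swr"] = stage_swr(session, truth, ens_res.ensembles,
                                          n_boot=n_boot, n_perm=n_perm,
                                          seed=seed)
            else:
                raise InfermapError(f"unknown stage {stage!r}")
        except InfermapError as e:
            raise InfermapError(f"stage {stage!r} failed: {e}") from e

    report["hash"] = report_hash({k: v for k, v in report.items()
                                  if k != "hash"})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "results.json").write_text(
            json.dumps(_round_floats(report), indent=1, sort_keys=True))
        lines = [f"infermap pipeline report (seed {seed})",
                 f"hash: {report['hash']}"]
        for k in stages:
            lines.append(f"[{k}] " + json.dumps(_round_floats(
                report.get(k, {})), sort_keys=True)[:2000])
        (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
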