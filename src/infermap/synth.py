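"""Synthetic multi-day session generator with planted ground truth.

The generator emulates the recording-day structure of the three-stage
sensory-preconditioning task: each day starts and ends with a sleep/rest
block, contains a reconditioning block (visual cue ``Yn`` followed by
outcome ``Zn``), inference-test blocks (auditory cue ``Xn`` alone) that are
interleaved with awake-rest gaps, and a short observational re-exposure
block (``Xn`` then ``Yn``).

Everything a downstream analysis will try to recover is planted explicitly
and reported in :class:`GroundTruth`:

* cue tuning          -- units multiply their baseline rate by ``1 + gain``
                         while their preferred cue is on;
* speed coupling      -- every unit adds ``speed_coupling * speed(t)`` Hz;
* decision points     -- on visit trials the animal pauses below 5 cm/s at a
                         known time before running to the outcome area;
* ripple coactivation -- configured unit tuples receive one injected spike
                         per participating sharp-wave/ripple, optionally in
                         a fixed order;
* pairwise spike lags -- during auditory cues, spikes of a trigger unit
                         elicit a target spike at a fixed millisecond lag.

Spike trains are inhomogeneous Poisson, generated by thinning, which is
exact and seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import LineString, Polygon

from .config import CUES, CUE_SET, SynthConfig, rng_for
from .errors import ValidationError
from .session import TRIAL_COLUMNS, LfpTrace, PositionTrace, SessionData

N_EARLY_DAYS = 4


@dataclass
class GroundTruth:
    """Planted structure of one synthetic session."""

    tuning: dict[int, str | None]                 # unit -> preferred cue
    baselines: dict[int, float]                   # unit -> baseline rate (Hz)
    swr: pd.DataFrame                             # start, end, day, context
    swr_participants: list[tuple[int, ...]]       # injected units per event
    pair_lags: dict[tuple[int, int], float]       # planted lags (ms)
    decision_points: dict[int, float | None]      # trial_id -> seconds
    visits: dict[int, bool]                       # trial_id -> entered area

    def tuned_units(self, cue: str) -> list[int]:
        return sorted(u for u, c in self.tuning.items() if c == cue)


# --------------------------------------------------------------------- #
# position model: piecewise-linear waypoint walk
# --------------------------------------------------------------------- #

class _Walk:
    """Waypoint-based trajectory builder.

    Positions are linear between waypoints, so speed is piecewise constant
    and fully controlled: wandering hops run at 6-15 cm/s, planted decision
    epochs sit still (0 cm/s), and dispenser approaches run at a fixed
    speed.  The walk never enters the outcome area except through
    :meth:`visit`.
    """

    def __init__(self, rng: np.random.Generator, cfg: SynthConfig):
        self.rng = rng
        self.cfg = cfg
        self.poly = np.asarray(cfg.outcome_area, float)
        polygon = Polygon(self.poly)
        self.block = polygon.buffer(0.5)        # legs must not cross this
        self.keepout = polygon.buffer(4.0)      # waypoints stay outside this
        w, h = cfg.arena
        self.margin = 2.0
        cx, cy = self.poly.mean(axis=0)
        self.center = np.array([cx, cy])
        arena_c = np.array([w / 2.0, h / 2.0])
        d = arena_c - self.center
        d = d / np.hypot(*d)
        # boundary crossing of the ray from the polygon centroid toward the
        # arena center; found by sampling (polygons are desk-scale)
        ss = np.linspace(0.0, max(w, h), 2048)
        pts = self.center[None, :] + ss[:, None] * d[None, :]
        outside = ~contains_xy(polygon, pts[:, 0], pts[:, 1])
        k = int(np.argmax(outside))
        self.boundary = pts[k]
        self.r_in = float(np.hypot(*(self.boundary - self.center)))
        self.stage_dist = 6.0
        self.stage = self.boundary + d * self.stage_dist   # pre-approach point
        self.exit_pt = self.boundary + d * 5.0
        self._pool: list[np.ndarray] = []
        start = self._sample()
        self.t = [0.0]
        self.x = [start[0]]
        self.y = [start[1]]

    # -- primitives ----------------------------------------------------- #

    def _sample(self) -> np.ndarray:
        while not self._pool:
            w, h = self.cfg.arena
            m = self.margin
            cand = np.column_stack([
                self.rng.uniform(m, w - m, 256),
                self.rng.uniform(m, h - m, 256),
            ])
            ok = ~contains_xy(self.keepout, cand[:, 0], cand[:, 1])
            self._pool = list(cand[ok])
        return self._pool.pop()

    def _leg_ok(self, a, b) -> bool:
        return not self.block.intersects(LineString([tuple(a), tuple(b)]))

    @property
    def now(self) -> float:
        return self.t[-1]

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x[-1], self.y[-1]])

    def _append(self, t: float, p) -> None:
        if t <= self.t[-1]:
            return
        self.t.append(float(t))
        self.x.append(float(p[0]))
        self.y.append(float(p[1]))

    def stay(self, until: float) -> None:
        self._append(until, self.pos)

    def goto(self, p, speed: float) -> float:
        d = float(np.hypot(*(np.asarray(p) - self.pos)))
        dur = d / speed if speed > 0 else 0.0
        self._append(self.now + max(dur, 1e-3), p)
        return self.now

    def goto_routed(self, p, speed: float) -> float:
        """goto with a detour through the arena center if the direct leg
        would cut through the outcome area."""
        if not self._leg_ok(self.pos, p):
            safe = np.array([self.cfg.arena[0] / 2.0, self.cfg.arena[1] / 2.0])
            if self._leg_ok(self.pos, safe):
                self.goto(safe, speed)
        return self.goto(p, speed)

    def wander(self, until: float) -> None:
        v0, v1 = self.cfg.mobile_speed
        while self.now < until - 1e-9:
            target = self._sample()
            for _ in range(8):
                if self._leg_ok(self.pos, target):
                    break
                target = self._sample()
            else:
                self.stay(until)    # stand still rather than cut the corner
                return
            v = self.rng.uniform(v0, v1)
            d = float(np.hypot(*(target - self.pos)))
            dur = max(d / v, 1e-3)
            rem = until - self.now
            if dur >= rem:
                frac = rem / dur
                target = self.pos + frac * (target - self.pos)
                self._append(until, target)
                return
            self._append(self.now + dur, target)

    def wander_to(self, until: float, target) -> None:
        """Wander, then arrive at ``target`` at (or just after) ``until``."""
        v0, v1 = self.cfg.mobile_speed
        target = np.asarray(target, float)
        while True:
            d = float(np.hypot(*(target - self.pos)))
            rem = until - self.now
            if rem <= d / v1 + 3.0:
                if rem <= 0 or d / rem > v1:
                    self.goto_routed(target, v1)   # slightly late arrival
                elif d / rem < v0 and d > 0.5:
                    self.stay(until - d / v0)
                    self.goto_routed(target, v0)
                elif d <= 0.5:
                    self.stay(until)
                else:
                    self.goto_routed(target, d / rem)
                self.stay(until)
                return
            hop = None
            for _ in range(12):
                cand = self._sample()
                # keep staging hops local so the final leg stays short
                cand = target + np.clip(cand - target, -14.0, 14.0)
                if (not contains_xy(self.keepout, cand[0], cand[1])
                        and self._leg_ok(self.pos, cand)
                        and self._leg_ok(cand, target)):
                    hop = cand
                    break
            if hop is None:
                self.stay(min(self.now + 1.0, until))
                continue
            v = self.rng.uniform(v0, v1)
            self._append(self.now + max(np.hypot(*(hop - self.pos)) / v, 1e-3), hop)

    # -- composite: one dispenser visit --------------------------------- #

    def visit(self, t_entry: float, t_leave: float, slow_s: float) -> float:
        """Pause below threshold, run to the dispenser, dwell, leave.

        Returns the planted decision point (end of the sub-threshold pause).
        The area is entered exactly at ``t_entry`` and left at ``t_leave``.
        """
        v = self.cfg.approach_speed
        t_dec = t_entry - self.stage_dist / v
        self.wander_to(t_dec - slow_s, self.stage)
        self.stay(t_dec)                                   # planted slow epoch
        self.goto(self.center, v)                          # crosses boundary at t_entry
        t_exit_start = max(self.now, t_leave - self.r_in / v)
        self.stay(t_exit_start)
        self.goto(self.exit_pt, v)                         # leaves area at ~t_leave
        return t_dec

    def build(self, fs: float, t_end: float) -> PositionTrace:
        self.stay(t_end)
        n = int(math.floor(t_end * fs)) + 1
        ts = np.arange(n) / fs
        xs = np.interp(ts, self.t, self.x)
        ys = np.interp(ts, self.t, self.y)
        return PositionTrace(ts, xs, ys, self.cfg.outcome_area)


# --------------------------------------------------------------------- #
# schedule
# --------------------------------------------------------------------- #

def _balanced_sets(rng: np.random.Generator, n: int) -> np.ndarray:
    sets = np.array([1, 2] * (n // 2) + ([1] if n % 2 else []))
    rng.shuffle(sets)
    return sets


def _build_schedule(cfg: SynthConfig, rng: np.random.Generator,
                    walk: _Walk) -> tuple[pd.DataFrame, pd.DataFrame,
                                          dict[int, float | None], dict[int, bool],
                                          np.ndarray]:
    """Lay out trials, epochs and the position walk for all days."""
    dur_x = cfg.cue_durations["auditory"]
    dur_y = cfg.cue_durations["visual"]
    dur_z = cfg.cue_durations["outcome"]
    post = cfg.post_cue_window

    rows: list[dict] = []
    epochs: list[dict] = []
    decisions: dict[int, float | None] = {}
    visits: dict[int, bool] = {}
    licks: list[float] = []
    tid = 0
    t = 0.0

    def add_licks(t_entry: float, t_leave: float) -> None:
        n = rng.poisson(cfg.lick_rate * max(t_leave - t_entry, 0.0))
        licks.extend(rng.uniform(t_entry, t_leave, n))

    def add_row(day, block, stage, cue, on, off, outcome_time=np.nan, correct=np.nan):
        nonlocal tid
        rows.append(dict(trial_id=tid, day=day, block=block, stage=stage,
                         cue=cue, set=CUE_SET[cue], onset=on, offset=off,
                         outcome_time=outcome_time, correct=correct))
        tid += 1
        return tid - 1

    def plan_visit(set_id: int) -> tuple[bool, float]:
        p = cfg.p_visit.get(set_id, 0.0)
        does = bool(rng.random() < p)
        occ_given = (cfg.occupancy.get(set_id, 0.0) / p) if p > 0 else 0.0
        return does, occ_given

    for day in range(1, cfg.n_days + 1):
        # morning sleep/rest block
        epochs.append(dict(day=day, context="sleep", start=t, end=t + cfg.rest_block_s))
        walk.stay(t + cfg.rest_block_s)
        t += cfg.rest_block_s
        task_start = t

        def close_task(upto):
            nonlocal task_start
            if upto > task_start:
                epochs.append(dict(day=day, context="task", start=task_start, end=upto))

        # reconditioning: Yn -> Zn
        n_cond = cfg.trials_per_day.get("conditioning", 0)
        for set_id in _balanced_sets(rng, n_cond):
            walk.wander(t + cfg.iti_s)
            t += cfg.iti_s
            y_on, y_off = t, t + dur_y
            z_on, z_off = y_off, y_off + dur_z
            yid = add_row(day, 0, "conditioning", f"Y{set_id}", y_on, y_off)
            zid = add_row(day, 0, "conditioning", f"Z{set_id}", z_on, z_off,
                          outcome_time=z_on)
            does, occ = plan_visit(set_id)
            visits[yid] = does
            visits[zid] = does
            if does:
                t_entry = y_off - max(occ * dur_y, 0.5)
                dec = walk.visit(t_entry, z_off - 2.0, cfg.decision_slow_s)
                add_licks(z_on, z_off - 2.0)
                decisions[yid] = dec
                decisions[zid] = None
            else:
                decisions[yid] = None
                decisions[zid] = None
            t = z_off
            walk.wander(t)

        # inference test blocks interleaved with awake rest
        n_test = cfg.trials_per_day.get("inference_test", 0)
        sets = _balanced_sets(rng, n_test)
        block_size = max(cfg.test_block_size, 1)
        for i, set_id in enumerate(sets):
            if i and i % block_size == 0:
                close_task(t)
                epochs.append(dict(day=day, context="awake_rest",
                                   start=t, end=t + cfg.awake_rest_s))
                walk.stay(t + cfg.awake_rest_s)
                t += cfg.awake_rest_s
                task_start = t
            walk.wander(t + cfg.iti_s)
            t += cfg.iti_s
            x_on, x_off = t, t + dur_x
            does, occ = plan_visit(set_id)
            correct = float((set_id == 1) == does)
            xid = add_row(day, 1 + i // block_size, "inference_test",
                          f"X{set_id}", x_on, x_off, correct=correct)
            visits[xid] = does
            if does:
                t_entry = x_on + 0.7 * dur_x
                t_leave = x_off + max(occ * post, 1.0)
                dec = walk.visit(t_entry, t_leave, cfg.decision_slow_s)
                add_licks(t_entry, t_leave)
                decisions[xid] = dec
            else:
                decisions[xid] = None
            t = x_off + post
            walk.wander(t)

        # observational re-exposure: Xn -> Yn, no outcome
        n_obs = cfg.trials_per_day.get("observational", 0)
        for set_id in _balanced_sets(rng, n_obs):
            walk.wander(t + cfg.iti_s)
            t += cfg.iti_s
            oid1 = add_row(day, 99, "observational", f"X{set_id}", t, t + dur_x)
            oid2 = add_row(day, 99, "observational", f"Y{set_id}",
                           t + dur_x, t + dur_x + dur_y)
            decisions[oid1] = decisions[oid2] = None
            visits[oid1] = visits[oid2] = False
            t += dur_x + dur_y
            walk.wander(t)

        close_task(t)
        # evening sleep/rest block
        epochs.append(dict(day=day, context="sleep", start=t, end=t + cfg.rest_block_s))
        walk.stay(t + cfg.rest_block_s)
        t += cfg.rest_block_s

    trials = pd.DataFrame(rows) if rows else pd.DataFrame(columns=TRIAL_COLUMNS)
    epochs_df = pd.DataFrame(epochs)
    return trials, epochs_df, decisions, visits, np.sort(np.asarray(licks))


# --------------------------------------------------------------------- #
# spikes
# --------------------------------------------------------------------- #

def _cue_windows(trials: pd.DataFrame, cue: str) -> np.ndarray:
    tr = trials[trials["cue"] == cue]
    return np.column_stack([tr["onset"].values, tr["offset"].values])


def _in_windows(t: np.ndarray, windows: np.ndarray) -> np.ndarray:
    if windows.size == 0:
        return np.zeros(t.shape, bool)
    order = np.argsort(windows[:, 0])
    starts = windows[order, 0]
    ends = windows[order, 1]
    idx = np.searchsorted(starts, t, side="right") - 1
    ok = idx >= 0
    res = np.zeros(t.shape, bool)
    res[ok] = t[ok] < ends[idx[ok]]
    return res


def _thin_unit(rng, t_end, base, gain, pref_windows, coupling,
               pos_t, speed, speed_max) -> np.ndarray:
    rmax = base * (1.0 + gain) + coupling * speed_max
    if rmax <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * t_end)
    cand = rng.uniform(0.0, t_end, n)
    rate = np.full(n, base)
    if gain > 0 and pref_windows is not None:
        rate = base * (1.0 + gain * _in_windows(cand, pref_windows))
    if coupling > 0:
        rate = rate + coupling * np.interp(cand, pos_t, speed)
    keep = rng.uniform(0.0, rmax, n) < rate
    return np.sort(cand[keep])


def _assign_tuning(cfg: SynthConfig, rng) -> dict[int, str | None]:
    per_cue = int(round(cfg.tuned_fraction * cfg.n_units))
    need = per_cue * len(CUES)
    if need > cfg.n_units:
        raise ValidationError(
            "tuned_fraction: too many tuned units for non-overlapping cue tuning"
        )
    perm = rng.permutation(cfg.n_units)
    tuning: dict[int, str | None] = {u: None for u in range(cfg.n_units)}
    k = 0
    for cue in CUES:
        for u in perm[k:k + per_cue]:
            tuning[int(u)] = cue
        k += per_cue
    return tuning


# --------------------------------------------------------------------- #
# ripples
# --------------------------------------------------------------------- #

def _plant_swrs(cfg: SynthConfig, rng, epochs: pd.DataFrame
                ) -> tuple[pd.DataFrame, list[tuple[int, ...]], dict[int, list[float]]]:
    """Draw ripple intervals in rest epochs and injected coactivation spikes."""
    starts, ends, days, ctxs = [], [], [], []
    participants: list[tuple[int, ...]] = []
    injected: dict[int, list[float]] = {}
    rest = epochs[epochs["context"].isin(["sleep", "awake_rest"])]
    for _, ep in rest.iterrows():
        usable = ep["end"] - ep["start"] - 1.0 - cfg.swr_duration
        if usable <= 0:
            continue
        n = rng.poisson(cfg.swr_rate * usable)
        if n == 0:
            continue
        t0 = np.sort(rng.uniform(ep["start"] + 0.5, ep["end"] - 0.5 - cfg.swr_duration, n))
        keep = np.concatenate([[True], np.diff(t0) > cfg.swr_duration + 0.1])
        t0 = t0[keep]
        for s in t0:
            e = s + cfg.swr_duration
            units_in: list[int] = []
            for cset in cfg.coactivation_sets:
                p = cset.probability(int(ep["day"]), N_EARLY_DAYS)
                if rng.random() >= p:
                    continue
                ordered = cset.order or ()
                lag = cset.order_lag_ms / 1000.0
                span = (len(ordered) - 1) * lag if ordered else 0.0
                base_t = rng.uniform(s + 0.002, max(e - span - 0.002, s + 0.003))
                for j, u in enumerate(ordered):
                    injected.setdefault(u, []).append(base_t + j * lag)
                for u in cset.units:
                    if u not in ordered:
                        injected.setdefault(u, []).append(rng.uniform(s, e))
                units_in.extend(cset.units)
            starts.append(s)
            ends.append(e)
            days.append(int(ep["day"]))
            ctxs.append(ep["context"])
            participants.append(tuple(sorted(set(units_in))))
    swr = pd.DataFrame(dict(start=starts, end=ends, day=days, context=ctxs))
    return swr, participants, injected


# --------------------------------------------------------------------- #
# public operations
# --------------------------------------------------------------------- #

def planted_tuning(cfg: SynthConfig) -> dict[int, str | None]:
    """The unit -> preferred-cue map a given config will produce.

    Exposed so callers can plant coactivation sets or spike lags on
    cue-tuned units before generating; the assignment depends only on the
    seed, the unit count and the tuned fraction.
    """
    return _assign_tuning(cfg, rng_for(cfg.seed, "units"))


def generate_session(cfg: SynthConfig) -> tuple[SessionData, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Same seed and config give byte-identical output.
    """
    cfg.validate()
    rng_sched = rng_for(cfg.seed, "schedule")
    rng_walk = rng_for(cfg.seed, "walk")
    rng_units = rng_for(cfg.seed, "units")
    rng_spk = rng_for(cfg.seed, "spikes")
    rng_swr = rng_for(cfg.seed, "swr")

    walk = _Walk(rng_walk, cfg)
    trials, epochs, decisions, visits, licks = _build_schedule(cfg, rng_sched, walk)
    t_end = float(epochs["end"].max())
    position = walk.build(cfg.position_fs, t_end)
    speed = position.speed
    speed_max = float(speed.max()) if speed.size else 0.0

    tuning = _assign_tuning(cfg, rng_units)
    if cfg.baseline_rate is not None:
        baselines = {u: float(cfg.baseline_rate) for u in range(cfg.n_units)}
    else:
        lo, hi = cfg.baseline_range
        mu, sigma = np.log(max(np.sqrt(lo * hi), 1e-3)), 0.5
        draws = np.exp(rng_units.normal(mu, sigma, cfg.n_units))
        baselines = {u: float(np.clip(r, lo, hi)) for u, r in enumerate(draws)}

    windows_by_cue = {cue: _cue_windows(trials, cue) for cue in CUES}

    spikes: dict[int, np.ndarray] = {}
    for u in range(cfg.n_units):
        pref = tuning[u]
        spikes[u] = _thin_unit(
            rng_spk, t_end, baselines[u],
            cfg.tuning_gain if pref else 0.0,
            windows_by_cue.get(pref) if pref else None,
            cfg.speed_coupling, position.t, speed, speed_max,
        )

    # planted millisecond lags during auditory cues of the inference test
    x_tr = trials[(trials["stage"] == "inference_test")]
    if cfg.lag_correct_only and len(x_tr):
        x_tr = x_tr[x_tr["correct"] == 1.0]
    x_windows = np.column_stack([x_tr["onset"].values, x_tr["offset"].values]) \
        if len(x_tr) else np.empty((0, 2))
    lag_spikes: dict[int, list[np.ndarray]] = {}
    for (a, b), lag_ms in cfg.planted_lag_ms.items():
        trig = spikes.get(a, np.empty(0))
        trig = trig[_in_windows(trig, x_windows)]
        sel = rng_spk.uniform(size=trig.size) < cfg.lag_prob
        t_new = trig[sel] + lag_ms / 1000.0
        if cfg.lag_jitter_ms > 0:
            t_new = t_new + rng_spk.normal(0.0, cfg.lag_jitter_ms / 1000.0, t_new.size)
        lag_spikes.setdefault(b, []).append(t_new)

    swr, participants, injected = _plant_swrs(cfg, rng_swr, epochs)

    res = cfg.spike_res
    for u in range(cfg.n_units):
        extra = lag_spikes.get(u, [])
        inj = injected.get(u, [])
        if extra or inj:
            allspk = np.concatenate([spikes[u], *extra, np.asarray(inj)])
        else:
            allspk = spikes[u]
        allspk = allspk[(allspk >= 0) & (allspk <= t_end)]
        spikes[u] = np.unique(np.round(allspk / res) * res)

    meta = dict(seed=cfg.seed, n_days=cfg.n_days, arena=list(cfg.arena),
                outcome_area=[list(p) for p in cfg.outcome_area],
                position_fs=cfg.position_fs,
                post_cue_window=cfg.post_cue_window)
    session = SessionData(spikes=spikes, trials=trials, position=position,
                          epochs=epochs, licks=licks, meta=meta)
    truth = GroundTruth(
        tuning=tuning, baselines=baselines, swr=swr,
        swr_participants=participants,
        pair_lags=dict(cfg.planted_lag_ms),
        decision_points=decisions, visits=visits,
    )
    return session, truth


def generate_lfp(cfg: SynthConfig, truth: GroundTruth,
                 t_end: float | None = None) -> LfpTrace:
    """Synthesize an LFP pair: pink noise plus ripple-band bursts.

    The detection channel carries, inside each ground-truth ripple
    interval, a Hann-windowed oscillation at ``cfg.burst_freq`` with
    amplitude ``cfg.lfp_snr`` times the background RMS.  The reference
    channel shares the common-mode noise but has no bursts, so
    common-mode subtraction leaves bursts plus independent channel noise.
    """
    if cfg.lfp_snr <= 0:
        raise ValidationError("lfp_snr must be > 0")
    rng = rng_for(cfg.seed, "lfp")
    if t_end is None:
        t_end = float(truth.swr["end"].max()) + 1.0 if len(truth.swr) else 10.0
    fs = cfg.lfp_fs
    n = int(round(t_end * fs))

    def pink(size: int) -> np.ndarray:
        white = rng.standard_normal(size)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(size, 1.0 / fs)
        f[0] = f[1] if size > 1 else 1.0
        spec /= np.sqrt(f)
        out = np.fft.irfft(spec, size)
        return out / out.std()

    common = pink(n)
    det = common + pink(n)
    ref = common + pink(n)
    amp = cfg.lfp_snr * 1.0   # own-channel background RMS is 1 by construction
    for s, e in truth.swr[["start", "end"]].itertuples(index=False):
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        i1 = min(i1, n)
        if i1 <= i0:
            continue
        tt = np.arange(i1 - i0) / fs
        env = np.hanning(i1 - i0)
        det[i0:i1] += amp * env * np.sin(2 * np.pi * cfg.burst_freq * tt)
    return LfpTrace(fs=fs, t0=0.0, data=det.astype(np.float32),
                    ref=ref.astype(np.float32))
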