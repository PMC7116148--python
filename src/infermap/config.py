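"""Configuration for the synthetic-session generator.

A :class:`SynthConfig` describes one simulated multi-day recording of the
three-stage sensory-preconditioning task: auditory cues ``X1/X2`` predict
visual cues ``Y1/Y2`` (observational learning), the visual cues predict a
rewarding (set 1) or neutral (set 2) outcome ``Z1/Z2`` (conditioning), and
auditory cues are finally presented alone (inference test).  The generator
plants known structure -- cue-tuned units, spike-time lags, ripple
coactivation schedules, decision points -- so that every downstream analysis
can be validated against ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError

CUES = ("X1", "X2", "Y1", "Y2", "Z1", "Z2")
AUDITORY = ("X1", "X2")
VISUAL = ("Y1", "Y2")
OUTCOME = ("Z1", "Z2")

#: cue -> set membership (set 1 is rewarded, set 2 neutral)
CUE_SET = {c: 1 if c.endswith("1") else 2 for c in CUES}

#: learned association maps used by the RSA association matrix
ASSOC_XY = {"X1": "Y1", "X2": "Y2"}
ASSOC_XZ = {"X1": "Z1", "X2": "Z2"}

#: speed (cm/s) below which the animal counts as immobile for ripple detection
IMMOBILITY_SPEED = 1.5
#: speed (cm/s) below which a time point can be a decision point
DECISION_SPEED = 5.0


@dataclass
class CoactivationSet:
    """A planted unit tuple that co-fires inside sharp-wave/ripples.

    Parameters
    ----------
    units
        Unit ids that receive one injected spike per participating event.
    p_early, p_late
        Per-event participation probability on early (days 1-4) and late
        (days 5-8) recording days.
    order
        Optional firing order for the injected spikes.  When given, the
        listed units fire sequentially with ``order_lag_ms`` between
        consecutive spikes; the remaining members fire at independent uniform
        times inside the event.
    order_lag_ms
        Spacing of the ordered injected spikes, in milliseconds.
    label
        Free-form tag (e.g. ``"set1"``) carried through to ground truth.
    """

    units: tuple[int, ...]
    p_early: float
    p_late: float
    order: tuple[int, ...] | None = None
    order_lag_ms: float = 5.0
    label: str = ""

    def probability(self, day: int, n_early_days: int = 4) -> float:
        return self.p_early if day <= n_early_days else self.p_late


def _default_trials() -> dict[str, int]:
    # presentations per day and stage; conditioning/inference counts follow
    # the recording-day protocol (>=24 reconditioning, 26 test trials)
    return {"observational": 6, "conditioning": 24, "inference_test": 26}


def _default_cue_durations() -> dict[str, float]:
    return {"auditory": 10.0, "visual": 8.0, "outcome": 10.0}


def _default_outcome_area() -> list[tuple[float, float]]:
    # rectangle in the dispenser corner of the 46 x 38 cm arena
    return [(34.0, 0.0), (46.0, 0.0), (46.0, 12.0), (34.0, 12.0)]


@dataclass
class SynthConfig:
    """Parameters of one synthetic multi-day session.  See module docstring."""

    n_units: int = 40
    n_days: int = 8
    trials_per_day: dict[str, int] = field(default_factory=_default_trials)
    cue_durations: dict[str, float] = field(default_factory=_default_cue_durations)

    # firing-rate model
    baseline_rate: float | None = None       # Hz; None -> lognormal in baseline_range
    baseline_range: tuple[float, float] = (0.5, 5.0)
    tuned_fraction: float = 0.08             # fraction of units tuned per cue
    tuning_gain: float = 5.0                 # multiplicative rate increase on preferred cue
    speed_coupling: float = 0.02             # Hz per cm/s, every unit

    # ripples
    swr_rate: float = 0.3                    # events/s during rest immobility
    swr_duration: float = 0.06               # s
    swr_band: tuple[float, float] = (135.0, 250.0)
    coactivation_sets: list[CoactivationSet] = field(default_factory=list)

    # planted millisecond-scale lags during auditory cues:
    # (trigger_unit, target_unit) -> lag in ms
    planted_lag_ms: dict[tuple[int, int], float] = field(default_factory=dict)
    lag_prob: float = 0.35                   # per trigger spike
    lag_jitter_ms: float = 0.2
    lag_correct_only: bool = True            # lags only on correct test trials

    # arena and behavior
    arena: tuple[float, float] = (46.0, 38.0)
    outcome_area: list[tuple[float, float]] = field(default_factory=_default_outcome_area)
    p_visit: dict[int, float] = field(default_factory=lambda: {1: 0.8, 2: 0.25})
    occupancy: dict[int, float] = field(default_factory=lambda: {1: 0.30, 2: 0.10})
    post_cue_window: float = 20.0            # s of reward-seeking window after X offset
    lick_rate: float = 7.0                   # Hz while dwelling at the dispenser
    mobile_speed: tuple[float, float] = (6.0, 15.0)   # cm/s wander range
    approach_speed: float = 12.0             # cm/s toward the dispenser
    decision_slow_s: float = 0.6             # planted sub-threshold epoch length

    # schedule
    iti_s: float = 5.0
    rest_block_s: float = 120.0              # sleep-box blocks at day start/end
    awake_rest_s: float = 60.0               # rest gaps between test blocks
    test_block_size: int = 9

    # acquisition
    position_fs: float = 25.0                # camera frame rate, Hz
    lfp_fs: float = 1000.0
    lfp_snr: float = 10.0                    # burst amplitude / background RMS
    burst_freq: float = 180.0                # Hz, inside swr_band
    spike_res: float = 1e-4                  # spike-time resolution, s

    seed: int = 0

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first invalid field."""
        if self.n_units < 1:
            raise ValidationError("n_units must be >= 1")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        for stage, n in self.trials_per_day.items():
            if n < 0:
                raise ValidationError(f"trials_per_day[{stage!r}] must be >= 0")
        for kind, dur in self.cue_durations.items():
            if dur <= 0:
                raise ValidationError(f"cue_durations[{kind!r}] must be > 0")
        if self.baseline_rate is not None and self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be positive")
        if not (0 <= self.baseline_range[0] <= self.baseline_range[1]):
            raise ValidationError("baseline_range must be 0 <= low <= high")
        if not 0.0 <= self.tuned_fraction <= 1.0:
            raise ValidationError("tuned_fraction must lie in [0, 1]")
        if self.tuning_gain < 0:
            raise ValidationError("tuning_gain must be >= 0")
        if self.speed_coupling < 0:
            raise ValidationError("speed_coupling must be >= 0")
        if self.swr_rate < 0:
            raise ValidationError("swr_rate must be >= 0")
        if self.swr_duration <= 0:
            raise ValidationError("swr_duration must be > 0")
        if not self.swr_band[0] < self.swr_band[1]:
            raise ValidationError("swr_band must satisfy low < high")
        if self.lfp_snr <= 0:
            raise ValidationError("lfp_snr must be > 0")
        if not self.swr_band[0] <= self.burst_freq <= self.swr_band[1]:
            raise ValidationError("burst_freq must lie inside swr_band")
        if self.lfp_fs < 2 * self.swr_band[1]:
            raise ValidationError("lfp_fs must be >= 2x the upper swr_band edge")
        for s in self.coactivation_sets:
            if not set(s.units) <= set(range(self.n_units)):
                raise ValidationError(
                    "coactivation_sets units must be valid unit ids"
                )
            if not (0 <= s.p_early <= 1 and 0 <= s.p_late <= 1):
                raise ValidationError(
                    "coactivation_sets probabilities must lie in [0, 1]"
                )
            if s.order is not None and not set(s.order) <= set(s.units):
                raise ValidationError(
                    "coactivation_sets order must be a subset of units"
                )
        for (a, b), lag in self.planted_lag_ms.items():
            if a == b:
                raise ValidationError("planted_lag_ms pairs must be distinct units")
        for key in (1, 2):
            pv = self.p_visit.get(key, 0.0)
            occ = self.occupancy.get(key, 0.0)
            if not 0 <= pv <= 1:
                raise ValidationError(f"p_visit[{key}] must lie in [0, 1]")
            if not 0 <= occ <= 1:
                raise ValidationError(f"occupancy[{key}] must lie in [0, 1]")
            if pv > 0 and occ / pv > 1:
                raise ValidationError(
                    f"occupancy[{key}] / p_visit[{key}] must be <= 1"
                )
        if self.position_fs <= 0:
            raise ValidationError("position_fs must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_lag_ms"] = {f"{a},{b}": v for (a, b), v in self.planted_lag_ms.items()}
        return d


def reference_recovery_config(seed: int = 0, **overrides) -> SynthConfig:
    """Reference condition for parameter-recovery checks.

    100 units, 8 planted per cue, tuning gain 5, 50 trials per cue on a
    single recording day.  Nuisance timings (inter-trial interval, rest
    lengths, post-cue window) are set to desk scale; they do not enter the
    recovery statistics.
    """
    cfg = SynthConfig(
        n_units=100,
        n_days=1,
        tuned_fraction=0.08,
        tuning_gain=5.0,
        trials_per_day={"observational": 0, "conditioning": 100,
                        "inference_test": 100},
        iti_s=2.0,
        post_cue_window=5.0,
        rest_block_s=30.0,
        awake_rest_s=20.0,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def rng_for(seed: int, *stream: str) -> np.random.Generator:
    """Deterministic child generator for a named random stream.

    Every stochastic stage derives its own stream from the global seed so
    that re-running one stage never perturbs another.
    """
    ints = [zlib.crc32(s.encode("utf8")) % (2**31) for s in stream]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *ints]))
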