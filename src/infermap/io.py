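"""Session directory layout: plain-text readers and writers.

A session directory contains::

    spikes.csv        unit_id, time_s           (sorted within unit)
    trials.csv        the trial table
    position.csv      t, x, y                   (25 Hz camera samples)
    epochs.csv        day, context, start, end  (sleep / task / awake_rest)
    licks.csv         time_s                    (optional)
    meta.json         day count, arena, outcome-area polygon, seed
    lfp.bin+lfp.json  float32 interleaved det/ref samples + header
      (or lfp.csv)    det, ref columns          (optional)
    ground_truth.json generator ground truth    (optional sidecar)

All times are seconds on a single session clock; intervals are half-open
``[start, end)``.  The loader round-trips the writer's output losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .session import (EPOCH_COLUMNS, TRIAL_COLUMNS, LfpTrace, PositionTrace,
                      SessionData)
from .synth import GroundTruth


def save_session(session: SessionData, path, truth: GroundTruth | None = None,
                 lfp_format: str = "bin") -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = [(u, t) for u in session.unit_ids for t in session.spikes[u]]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        path / "spikes.csv", index=False)
    session.trials.to_csv(path / "trials.csv", index=False)
    pos = session.position
    pd.DataFrame(dict(t=pos.t, x=pos.x, y=pos.y)).to_csv(
        path / "position.csv", index=False)
    session.epochs.to_csv(path / "epochs.csv", index=False)
    pd.DataFrame(dict(time_s=session.licks)).to_csv(
        path / "licks.csv", index=False)
    meta = dict(session.meta)
    meta.setdefault("outcome_area", [list(p) for p in pos.outcome_area])
    meta["n_units"] = session.n_units
    (path / "meta.json").write_text(json.dumps(meta, indent=1))

    if session.lfp is not None:
        lfp = session.lfp
        header = dict(fs=lfp.fs, t0=lfp.t0, n=len(lfp.data),
                      channels=["det", "ref"], format=lfp_format)
        (path / "lfp.json").write_text(json.dumps(header))
        if lfp_format == "bin":
            inter = np.empty(2 * len(lfp.data), np.float32)
            inter[0::2] = lfp.data
            inter[1::2] = lfp.ref
            inter.tofile(path / "lfp.bin")
        else:
            pd.DataFrame(dict(det=lfp.data, ref=lfp.ref)).to_csv(
                path / "lfp.csv", index=False)

    if truth is not None:
        (path / "ground_truth.json").write_text(json.dumps(
            _truth_to_json(truth), indent=1))
    return path


def _truth_to_json(truth: GroundTruth) -> dict:
    return dict(
        tuning={str(u): c for u, c in truth.tuning.items()},
        baselines={str(u): b for u, b in truth.baselines.items()},
        swr=truth.swr.to_dict(orient="list"),
        swr_participants=[list(map(int, p)) for p in truth.swr_participants],
        pair_lags={f"{a},{b}": v for (a, b), v in truth.pair_lags.items()},
        decision_points={str(k): v for k, v in truth.decision_points.items()},
        visits={str(k): bool(v) for k, v in truth.visits.items()},
    )


def load_ground_truth(path) -> GroundTruth:
    d = json.loads((Path(path) / "ground_truth.json").read_text())
    return GroundTruth(
        tuning={int(u): c for u, c in d["tuning"].items()},
        baselines={int(u): b for u, b in d["baselines"].items()},
        swr=pd.DataFrame(d["swr"]),
        swr_participants=[tuple(p) for p in d["swr_participants"]],
        pair_lags={tuple(map(int, k.split(","))): v
                   for k, v in d["pair_lags"].items()},
        decision_points={int(k): v for k, v in d["decision_points"].items()},
        visits={int(k): v for k, v in d["visits"].items()},
    )


def _require(path: Path, name: str) -> Path:
    p = path / name
    if not p.exists():
        raise SchemaError(f"missing session file: {name}")
    return p


def load_session(path) -> SessionData:
    """Load and validate a session directory.

    Raises :class:`SchemaError` with a specific message per defect
    (missing file, bad schema, non-monotone timestamps, ...).
    """
    path = Path(path)
    meta = json.loads(_require(path, "meta.json").read_text())

    sp = pd.read_csv(_require(path, "spikes.csv"), float_precision="round_trip")
    if list(sp.columns) != ["unit_id", "time_s"]:
        raise SchemaError("spikes.csv must have columns unit_id, time_s")
    spikes: dict[int, np.ndarray] = {}
    for u, grp in sp.groupby("unit_id"):
        t = grp["time_s"].values.astype(float)
        if np.any(np.diff(t) < 0):
            raise SchemaError(f"spikes.csv: unit {u} times not sorted")
        spikes[int(u)] = t
    for u in range(int(meta.get("n_units", 0))):
        spikes.setdefault(u, np.empty(0))

    trials = pd.read_csv(_require(path, "trials.csv"), float_precision="round_trip")
    if trials.empty and not list(trials.columns):
        trials = pd.DataFrame(columns=TRIAL_COLUMNS)

    posf = pd.read_csv(_require(path, "position.csv"), float_precision="round_trip")
    if not {"t", "x", "y"} <= set(posf.columns):
        raise SchemaError("position.csv must have columns t, x, y")
    position = PositionTrace(posf["t"].values, posf["x"].values,
                             posf["y"].values,
                             [tuple(p) for p in meta.get("outcome_area", [])])

    ef = path / "epochs.csv"
    epochs = pd.read_csv(ef, float_precision="round_trip") if ef.exists() else pd.DataFrame(columns=EPOCH_COLUMNS)

    lick_f = path / "licks.csv"
    licks = (pd.read_csv(lick_f, float_precision="round_trip")["time_s"].values
             if lick_f.exists() else np.empty(0))

    lfp = None
    hf = path / "lfp.json"
    if hf.exists():
        header = json.loads(hf.read_text())
        if header.get("format") == "bin":
            raw = np.fromfile(path / "lfp.bin", dtype=np.float32)
            if raw.size != 2 * header["n"]:
                raise SchemaError("lfp.bin length disagrees with lfp.json")
            lfp = LfpTrace(header["fs"], header["t0"], raw[0::2], raw[1::2])
        else:
            lf = pd.read_csv(path / "lfp.csv", float_precision="round_trip")
            lfp = LfpTrace(header["fs"], header["t0"],
                           lf["det"].values.astype(np.float32),
                           lf["ref"].values.astype(np.float32))

    session = SessionData(spikes=spikes, trials=trials, position=position,
                          epochs=epochs, lfp=lfp, licks=np.sort(licks),
                          meta=meta)
    session.validate()
    return session


def write_swr_events(swrs, path) -> Path:
    """BED-like tab-separated interval file (seconds)."""
    path = Path(path)
    ev = swrs.events[["start", "end", "peak_sd", "context"]]
    ev.to_csv(path, sep="\t", index=False)
    return path


def write_participation(part, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(part.counts, columns=[f"u{u}" for u in part.units])
    df.insert(0, "start", part.events["start"].values)
    df.insert(1, "end", part.events["end"].values)
    df.to_csv(path, index=False)
    return path
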