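"""Session directory I/O and schema validation.

A session directory holds plain, diffable formats on one clock (seconds):

* ``position.csv`` — t_s, x_cm, y_cm
* ``spikes.csv`` — cell_id, t_s
* ``lfp.bin`` + ``lfp.json`` — little-endian float32 voltages and metadata
  (fs_hz, n_samples, units_uV, t0_s)
* ``laps.csv`` — lap_id, t_start_s, t_end_s
* ``ground_truth.json`` — simulator config, seed, per-cell truth and burst
  list (present only for synthetic sessions)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Session


def write_session(session: Session, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pos = session.position
    pd.DataFrame({"t_s": pos.t, "x_cm": pos.x, "y_cm": pos.y}).to_csv(
        out / "position.csv", index=False)
    session.spikes.rename(columns={"t": "t_s"}).to_csv(out / "spikes.csv", index=False)
    lfp = session.lfp
    lfp.lfp.astype("<f4").tofile(out / "lfp.bin")
    with open(out / "lfp.json", "w") as fh:
        json.dump({"fs_hz": lfp.fs, "n_samples": int(lfp.lfp.size),
                   "units_uV": True, "t0_s": float(lfp.t[0])}, fh, indent=2)
    pd.DataFrame([{"lap_id": i, "t_start_s": a, "t_end_s": b}
                  for i, (a, b) in enumerate(pos.laps)]).to_csv(
        out / "laps.csv", index=False)
    truth = {
        "config": _jsonable(asdict(session.config)),
        "cells": _jsonable(session.cells.to_dict(orient="list")),
        "bursts": _jsonable(lfp.bursts.to_dict(orient="list")),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


@dataclass
class LoadedSession:
    """A session read back from disk (no ground-truth phase series)."""

    position: pd.DataFrame   # t_s, x_cm, y_cm
    spikes: pd.DataFrame     # cell_id, t_s
    lfp: np.ndarray
    lfp_fs: float
    lfp_t0: float
    laps: list
    ground_truth: dict | None = None

    @property
    def lfp_t(self):
        return self.lfp_t0 + np.arange(self.lfp.size) / self.lfp_fs


def read_session(session_dir) -> LoadedSession:
    d = Path(session_dir)
    position = pd.read_csv(d / "position.csv")
    spikes = pd.read_csv(d / "spikes.csv")
    with open(d / "lfp.json") as fh:
        meta = json.load(fh)
    lfp = np.fromfile(d / "lfp.bin", dtype="<f4").astype(float)
    laps_df = pd.read_csv(d / "laps.csv")
    laps = [(row.t_start_s, row.t_end_s) for row in laps_df.itertuples()]
    truth = None
    gt = d / "ground_truth.json"
    if gt.exists():
        with open(gt) as fh:
            truth = json.load(fh)
    return LoadedSession(position=position, spikes=spikes, lfp=lfp,
                         lfp_fs=float(meta["fs_hz"]), lfp_t0=float(meta.get("t0_s", 0.0)),
                         laps=laps, ground_truth=truth)


def validate_session(session_dir) -> list:
    """Schema and clock checks; returns a list of failure strings (empty = pass)."""
    d = Path(session_dir)
    problems = []
    for name in ("position.csv", "spikes.csv", "lfp.bin", "lfp.json", "laps.csv"):
        if not (d / name).exists():
            problems.append(f"missing file: {name}")
    if problems:
        return problems
    s = read_session(d)
    t = s.position["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        problems.append("position timestamps not strictly increasing")
    with open(d / "lfp.json") as fh:
        meta = json.load(fh)
    if int(meta["n_samples"]) != s.lfp.size:
        problems.append("lfp.json n_samples does not match lfp.bin")
    lfp_end = s.lfp_t0 + s.lfp.size / s.lfp_fs
    pos_end = t[-1]
    if abs(lfp_end - pos_end) > 1.0:
        problems.append("LFP duration inconsistent with position record")
    st = s.spikes["t_s"].to_numpy()
    if st.size and (st.min() < s.lfp_t0 - 1e-9 or st.max() > lfp_end + 1e-9):
        problems.append("spikes outside the LFP record")
    for a, b in s.laps:
        if not (t[0] - 1e-9 <= a < b <= pos_end + 1e-9):
            problems.append(f"lap ({a}, {b}) not contained in the session")
    return problems
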