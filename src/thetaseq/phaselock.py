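"""Spike-phase assignment and FG/NFG cell classification.

Each running spike is matched to the nearest LFP sample to read off its
theta, slow-gamma and fast-gamma phase.  A place cell is an FG-cell if the
Rayleigh test on its fast-gamma phase distribution is significant (pooled
across laps) and it fired at least 10 spikes in every lap; an NFG-cell
satisfies the spike criterion without fast-gamma significance.  Cells
failing the per-lap spike criterion stay unclassified and are excluded
from both pools downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circstats import mean_vector_length, circular_mean_deg, rayleigh_test


def assign_spike_phases(spikes: pd.DataFrame, t_lfp, phases: dict, laps,
                        speed_t=None, speed=None, episodes=None) -> pd.DataFrame:
    """Build the spike-phase table for on-track spikes.

    Parameters
    ----------
    spikes : DataFrame with columns ``cell_id`` and ``t``
    t_lfp : LFP sample times (uniform grid)
    phases : mapping of name -> per-sample phase series in degrees, e.g.
        ``{"theta": ..., "slow": ..., "fast": ...}``
    laps : list of (t_start, t_end); spikes outside every lap (rest box)
        are excluded
    speed_t, speed : optional kinematics used to attach a running speed to
        each spike (linear interpolation)
    episodes : optional list of GammaEpisode used to flag spikes inside
        detected slow/fast episodes

    Returns
    -------
    DataFrame with cell_id, t, lap, one ``<name>_phase_deg`` column per
    phase series, ``speed`` (if given) and ``in_slow_episode`` /
    ``in_fast_episode`` flags (if episodes given).
    """
    t_lfp = np.asarray(t_lfp, dtype=float)
    st = spikes["t"].to_numpy(dtype=float)
    cid = spikes["cell_id"].to_numpy()

    fs = 1.0 / np.median(np.diff(t_lfp))
    inside = (st >= t_lfp[0]) & (st <= t_lfp[-1])
    n_dropped = int((~inside).sum())

    lap_id = np.full(st.size, -1, dtype=int)
    for i, (a, b) in enumerate(laps):
        lap_id[(st >= a) & (st < b)] = i
    keep = inside & (lap_id >= 0)

    st_k = st[keep]
    idx = np.clip(np.round((st_k - t_lfp[0]) * fs).astype(int), 0, t_lfp.size - 1)
    out = {"cell_id": cid[keep], "t": st_k, "lap": lap_id[keep]}
    for name, series in phases.items():
        out[f"{name}_phase_deg"] = np.asarray(series, dtype=float)[idx]
    if speed is not None:
        out["speed"] = np.interp(st_k, np.asarray(speed_t, float),
                                 np.asarray(speed, float))
    table = pd.DataFrame(out)
    if episodes is not None:
        for rhythm in ("slow", "fast"):
            flag = np.zeros(len(table), dtype=bool)
            for ep in episodes:
                if ep.rhythm != rhythm:
                    continue
                flag |= (st_k >= ep.t_start) & (st_k <= ep.t_end)
            table[f"in_{rhythm}_episode"] = flag
    table.attrs["n_dropped_outside_lfp"] = n_dropped
    return table


def classify_cells(table: pd.DataFrame, n_laps, alpha=0.05,
                   min_spikes_per_lap=10, speed_min=None) -> pd.DataFrame:
    """Per-cell phase-locking profile and FG/NFG label.

    The Rayleigh test is applied to spikes pooled across laps; the per-lap
    spike criterion gates which cells can be labeled at all.  Slow-gamma
    locking is reported but never used for the label.
    """
    tab = table
    if speed_min is not None and "speed" in tab:
        tab = tab[tab["speed"] > speed_min]
    rows = []
    for cell_id, grp in tab.groupby("cell_id"):
        lap_counts = grp.groupby("lap").size().reindex(range(n_laps), fill_value=0)
        enough = bool((lap_counts >= min_spikes_per_lap).all())
        fast = grp["fast_phase_deg"].to_numpy()
        slow = grp["slow_phase_deg"].to_numpy() if "slow_phase_deg" in grp else None
        row = {"cell_id": cell_id, "n_spikes": len(grp),
               "min_lap_spikes": int(lap_counts.min())}
        if fast.size >= 2:
            res = rayleigh_test(fast)
            row.update(r_fast=mean_vector_length(fast), p_fast=res.pvalue,
                       pref_fast_deg=circular_mean_deg(fast))
        else:
            row.update(r_fast=np.nan, p_fast=np.nan, pref_fast_deg=np.nan)
        if slow is not None and slow.size >= 2:
            res_s = rayleigh_test(slow)
            row.update(r_slow=mean_vector_length(slow), p_slow=res_s.pvalue,
                       pref_slow_deg=circular_mean_deg(slow))
        else:
            row.update(r_slow=np.nan, p_slow=np.nan, pref_slow_deg=np.nan)
        if not enough or not np.isfinite(row["p_fast"]):
            row["label"] = "unclassified"
        elif row["p_fast"] < alpha:
            row["label"] = "FG"
        else:
            row["label"] = "NFG"
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")


def per_lap_locking(table: pd.DataFrame, n_laps, phase_col="fast_phase_deg",
                    speed_min=None) -> pd.DataFrame:
    """Mean vector length per (cell, lap); NaN where a lap has no spikes."""
    tab = table
    if speed_min is not None and "speed" in tab:
        tab = tab[tab["speed"] > speed_min]
    cells = sorted(tab["cell_id"].unique())
    out = pd.DataFrame(np.nan, index=cells, columns=range(n_laps))
    for (cell_id, lap), grp in tab.groupby(["cell_id", "lap"]):
        if len(grp) >= 1:
            out.loc[cell_id, lap] = mean_vector_length(grp[phase_col].to_numpy())
    return out
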