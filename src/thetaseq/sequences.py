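"""Theta-sequence detection and the weighted-correlation statistic.

A theta sequence is one theta cycle's decoded posterior restricted to a
window of +/-35 cm (10 bins of ~3.5 cm) around the animal's current
position and +/-30 ms (at the 5-ms posterior step) around the cycle's
mid-time: a 13 x 21 probability submatrix.  The weighted correlation

    corr_w(t, p; prob) = cov(t, p; prob) / sqrt(cov(t,t; prob) cov(p,p; prob))

with probability-weighted means and covariances quantifies the sweep
structure: positive for forward (behind -> ahead) sweeps.

Sequence inclusion follows the study criteria: the animal is on the usable
track segment at speed > 5 cm/s throughout the cycle, the cycle lasts
100-200 ms, and enough place cells participate (by default >= 4 distinct
accepted cells firing with >= 5 spikes in total; a stricter reading -
every counted cell fires >= 5 spikes - sits behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .decoding import Posterior
from .signals import ThetaCycles, segment_theta_cycles


def weighted_correlation(prob, t=None, p=None):
    """Probability-weighted Pearson correlation of time and position.

    ``prob`` is a nonnegative (n_t, n_p) matrix; ``t`` and ``p`` default to
    bin indices.  Returns NaN when the weighted variance of either axis
    vanishes (or all probabilities are zero).
    """
    w = np.asarray(prob, dtype=float)
    if w.ndim != 2:
        raise ValueError("prob must be 2-D")
    if np.any(w < 0):
        raise ValueError("negative probabilities")
    nt, npos = w.shape
    tv = np.arange(nt, dtype=float) if t is None else np.asarray(t, dtype=float)
    pv = np.arange(npos, dtype=float) if p is None else np.asarray(p, dtype=float)
    out = weighted_correlation_batch(w[None], tv, pv)
    return float(out[0])


def weighted_correlation_batch(prob_stack, t, p):
    """Vectorized corr_w over a stack of (n_t, n_p) matrices."""
    w = np.asarray(prob_stack, dtype=float)
    tv = np.asarray(t, dtype=float)[None, :, None]
    pv = np.asarray(p, dtype=float)[None, None, :]
    sw = w.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        mt = (w * tv).sum(axis=(1, 2)) / sw
        mp = (w * pv).sum(axis=(1, 2)) / sw
        dt = tv - mt[:, None, None]
        dp = pv - mp[:, None, None]
        cov_tp = (w * dt * dp).sum(axis=(1, 2)) / sw
        cov_tt = (w * dt * dt).sum(axis=(1, 2)) / sw
        cov_pp = (w * dp * dp).sum(axis=(1, 2)) / sw
        denom = np.sqrt(cov_tt * cov_pp)
        corr = np.where(denom > 0, cov_tp / np.where(denom > 0, denom, 1.0), np.nan)
    corr = np.where(sw > 0, corr, np.nan)
    return corr


@dataclass
class SequenceContext:
    """Behavioral context shared by sequence detection calls."""

    pos_t: np.ndarray
    angle_unwrapped_deg: np.ndarray
    speed: np.ndarray
    accepted_cells: np.ndarray        # cell ids accepted as place cells
    config: PipelineConfig
    direction_sign: int = 1           # +1 when angle increases in the running direction

    def angle_at(self, times):
        return np.interp(times, self.pos_t, self.angle_unwrapped_deg)

    def speed_at(self, times):
        return np.interp(times, self.pos_t, self.speed)


def _cycle_min_speed(ctx: SequenceContext, t0, t1, n_probe=9):
    probes = np.linspace(t0, t1, n_probe)
    return ctx.speed_at(probes).min(axis=0)


def detect_sequences(cycles: ThetaCycles, posteriors: dict,
                     spike_table: pd.DataFrame, ctx: SequenceContext,
                     variants_for_corr=None) -> pd.DataFrame:
    """Apply the sequence inclusion criteria and score each kept cycle.

    ``posteriors`` maps variant name -> :class:`Posterior`; corr_w columns
    ``corr_<variant>`` are computed for each requested variant (all by
    default) on the same theta cycles, which are selected using criteria
    evaluated on behavior and spikes only.

    Returns one row per kept sequence with its cycle id, timing, lap-free
    behavioral fields, participation counts and corr_w values, plus a
    ``drop_reason`` accounting in ``DataFrame.attrs["n_dropped"]``.
    """
    cfg = ctx.config
    if variants_for_corr is None:
        variants_for_corr = list(posteriors)
    n = len(cycles)
    dropped = {"invalid_cycle": 0, "duration": 0, "speed": 0, "track_edge": 0,
               "participation": 0, "window_gap": 0}
    if n == 0:
        df = pd.DataFrame()
        df.attrs["n_dropped"] = dropped
        return df

    t0 = cycles.t_start
    t1 = cycles.t_end
    dur = t1 - t0
    keep = cycles.valid.copy()
    dropped["invalid_cycle"] = int((~keep).sum())
    m = (dur >= cfg.seq_min_duration_s) & (dur <= cfg.seq_max_duration_s)
    dropped["duration"] = int((keep & ~m).sum())
    keep &= m

    # speed > 5 cm/s throughout the cycle
    probes = np.linspace(t0, t1, 9)
    vmin = np.interp(probes, ctx.pos_t, ctx.speed).min(axis=0)
    m = vmin > cfg.speed_min
    dropped["speed"] = int((keep & ~m).sum())
    keep &= m

    # on the usable track segment, with room for the spatial window
    t_mid = cycles.t_mid
    ang_mid = ctx.angle_at(t_mid) % 360.0
    bin_deg = 360.0 / cfg.n_pos_bins
    margin = cfg.seq_spatial_halfwidth_bins * bin_deg
    m = ((ang_mid - margin >= cfg.track_start_deg)
         & (ang_mid + margin <= cfg.track_end_deg))
    dropped["track_edge"] = int((keep & ~m).sum())
    keep &= m

    # participation: spikes of accepted place cells inside the cycle
    acc = np.isin(spike_table["cell_id"].to_numpy(), ctx.accepted_cells)
    st = spike_table["t"].to_numpy()[acc]
    sc = spike_table["cell_id"].to_numpy()[acc]
    order = np.argsort(st, kind="mergesort")
    st, sc = st[order], sc[order]
    ci = np.searchsorted(t0, st, side="right") - 1
    inside = (ci >= 0) & (st < t1[np.clip(ci, 0, n - 1)])
    ci, sc_in = ci[inside], sc[inside]
    n_cells = np.zeros(n, dtype=int)
    n_spikes = np.zeros(n, dtype=int)
    max_cell_spikes = np.zeros(n, dtype=int)
    cells_ge5 = np.zeros(n, dtype=int)
    if ci.size:
        grp = pd.DataFrame({"cyc": ci, "cell": sc_in}).groupby(["cyc", "cell"]).size()
        per_cyc = grp.groupby(level=0)
        n_cells[per_cyc.size().index] = per_cyc.size().to_numpy()
        n_spikes[per_cyc.sum().index] = per_cyc.sum().to_numpy()
        max_cell_spikes[per_cyc.max().index] = per_cyc.max().to_numpy()
        ge5 = (grp >= cfg.seq_min_spikes).groupby(level=0).sum()
        cells_ge5[ge5.index] = ge5.to_numpy()
    if cfg.strict_participation:
        m = cells_ge5 >= cfg.seq_min_cells
    else:
        m = (n_cells >= cfg.seq_min_cells) & (n_spikes >= cfg.seq_min_spikes)
    dropped["participation"] = int((keep & ~m).sum())
    keep &= m

    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        df = pd.DataFrame()
        df.attrs["n_dropped"] = dropped
        return df

    center_bin = np.clip((ang_mid[idx] / bin_deg).astype(int), 0, cfg.n_pos_bins - 1)
    out = pd.DataFrame({
        "cycle_id": idx,
        "t_start": t0[idx], "t_end": t1[idx], "t_mid": t_mid[idx],
        "duration": dur[idx],
        "angle_deg": ang_mid[idx],
        "center_bin": center_bin,
        "n_cells": n_cells[idx], "n_spikes": n_spikes[idx],
    })

    # corr_w per decoder variant on the +/-30 ms x +/-35 cm window
    half_t = cfg.seq_temporal_halfwidth_s
    kept_gap = np.ones(idx.size, dtype=bool)
    for name in variants_for_corr:
        post: Posterior = posteriors[name]
        corr, ok = _score_windows(post, out["t_mid"].to_numpy(), center_bin, ctx, cfg)
        out[f"corr_{name}"] = corr
        kept_gap &= ok
    dropped["window_gap"] = int((~kept_gap).sum())
    out = out[kept_gap].reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


def _score_windows(post: Posterior, t_mid, center_bin, ctx: SequenceContext,
                   cfg: PipelineConfig):
    """corr_w of the sequence windows against one posterior variant."""
    n_seq = t_mid.size
    corr = np.full(n_seq, np.nan)
    ok = np.zeros(n_seq, dtype=bool)
    if post.centers.size == 0:
        return corr, ok
    n_t = int(round(2 * cfg.seq_temporal_halfwidth_s / cfg.decode_step_s)) + 1  # 13
    half_bins = (n_t - 1) // 2
    i_mid = np.clip(np.searchsorted(post.centers, t_mid), 0, post.centers.size - 1)
    # nearest center
    i_alt = np.clip(i_mid - 1, 0, post.centers.size - 1)
    i_mid = np.where(np.abs(post.centers[i_alt] - t_mid)
                     < np.abs(post.centers[i_mid] - t_mid), i_alt, i_mid)
    lo = i_mid - half_bins
    hi = i_mid + half_bins
    in_range = (lo >= 0) & (hi < post.centers.size)
    # windows must be contiguous at the decoding step (no running-gap seams)
    span_ok = np.zeros(n_seq, dtype=bool)
    span = 2 * cfg.seq_temporal_halfwidth_s
    span_ok[in_range] = np.abs((post.centers[hi[in_range]]
                                - post.centers[lo[in_range]]) - span) < 1e-6
    ok[:] = in_range & span_ok
    if not np.any(ok):
        return corr, ok
    t_idx = lo[ok, None] + np.arange(n_t)[None, :]
    offs = ctx.direction_sign * np.arange(-cfg.seq_spatial_halfwidth_bins,
                                          cfg.seq_spatial_halfwidth_bins + 1)
    p_idx = (center_bin[ok, None] + offs[None, :]) % cfg.n_pos_bins
    sub = post.P[t_idx[:, :, None], p_idx[:, None, :]]
    pvals = np.arange(-cfg.seq_spatial_halfwidth_bins,
                      cfg.seq_spatial_halfwidth_bins + 1, dtype=float)
    corr[ok] = weighted_correlation_batch(sub, np.arange(n_t, dtype=float), pvals)
    return corr, ok


def optimize_cut_phase(t_lfp, theta_phase_deg, posterior_raw: Posterior,
                       spike_table: pd.DataFrame, ctx: SequenceContext):
    """Find the theta cutting phase that maximizes mean corr_w.

    Candidate phases step through 0, 10, ..., 350 degrees; for each, cycles
    are segmented, sequences detected, and the raw-decoder weighted
    correlations averaged.  Returns ``(best_phase_deg, profile)`` where the
    profile table lists mean corr_w and sequence counts per phase.  Ties
    break toward the smallest phase; an error is raised when no phase
    yields the minimum number of sequences.
    """
    cfg = ctx.config
    phases = np.arange(0.0, 360.0, cfg.cut_phase_step_deg)
    rows = []
    for ph in phases:
        cycles = segment_theta_cycles(t_lfp, theta_phase_deg, cut_phase_deg=ph)
        seqs = detect_sequences(cycles, {"raw": posterior_raw}, spike_table, ctx,
                                variants_for_corr=["raw"])
        n_seq = len(seqs)
        mean_corr = float(np.nanmean(seqs["corr_raw"])) if n_seq else np.nan
        rows.append({"cut_phase_deg": ph, "n_sequences": n_seq,
                     "mean_corr": mean_corr})
    profile = pd.DataFrame(rows)
    usable = profile[(profile["n_sequences"] >= cfg.min_sequences_for_cut)
                     & np.isfinite(profile["mean_corr"])]
    if usable.empty:
        raise ValueError("no cutting phase yields enough theta sequences")
    best = usable.loc[usable["mean_corr"].idxmax()]
    # idxmax returns the first maximum, i.e. the smallest phase on ties
    return float(best["cut_phase_deg"]), profile


def label_sequence_dominance(seq_row, spike_table: pd.DataFrame,
                             sg_cycle_of_spike, fg_cells, accepted_cells,
                             min_sg_cycles=3):
    """Label one sequence FG / NFG / neither.

    FG-cell sequence: at least one FG place cell fires, and some individual
    cell fires across >= ``min_sg_cycles`` distinct slow-gamma cycles.
    NFG-cell sequence: no FG cell fires and the same cycle-span condition
    holds.  Otherwise "neither".
    """
    st = spike_table["t"].to_numpy()
    sc = spike_table["cell_id"].to_numpy()
    m = (st >= seq_row["t_start"]) & (st < seq_row["t_end"]) & np.isin(sc, accepted_cells)
    if not np.any(m):
        return "neither"
    cells = sc[m]
    cyc = np.asarray(sg_cycle_of_spike)[m]
    span_ok = False
    for c in np.unique(cells):
        if np.unique(cyc[cells == c]).size >= min_sg_cycles:
            span_ok = True
            break
    if not span_ok:
        return "neither"
    has_fg = bool(np.isin(cells, fg_cells).any())
    return "FG" if has_fg else "NFG"
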