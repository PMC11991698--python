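"""End-to-end session analysis: behavior -> signals -> cells -> decoding ->
theta sequences -> slow-gamma phase precession.

The driver accepts either an in-memory synthetic :class:`~thetaseq.synthetic.Session`
or a session directory on disk, runs every stage in dependency order with
the printed-constant defaults in :class:`~thetaseq.config.PipelineConfig`,
and returns a :class:`SessionResult` whose ``summary()`` is JSON-ready.
Every stochastic stage (exNFG downsampling, shuffle nulls) draws from a
substream of the master seed, so reruns with identical inputs are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import placecells, signals
from .config import PipelineConfig
from .decoding import (Posterior, build_decoder, decode_session,
                       make_exclusion_decoders)
from .phaselock import assign_spike_phases, classify_cells
from .precession import (ShiftData, build_shift_data, quadrant_analysis,
                         sg_trough_times, shuffle_null)
from .sequences import (SequenceContext, detect_sequences, label_sequence_dominance,
                        optimize_cut_phase)
from .signals import (bandpass, detect_gamma_episodes, flag_slow_gamma_event_cycles,
                      instantaneous_phase, morlet_band_power, segment_theta_cycles,
                      zscore_in_intervals)
from .synthetic import Session


@dataclass
class SessionResult:
    """Everything a session analysis produces, keyed by stage."""

    config: PipelineConfig
    seed: int
    laps: list
    kin: dict = field(default_factory=dict)          # t, angle_deg, angle_unwrapped, speed
    phases: dict = field(default_factory=dict)       # theta/slow/fast phase series
    z_power: dict = field(default_factory=dict)      # slow/fast z series
    episodes: list = field(default_factory=list)
    cycles: object = None
    cut_phase_deg: float = 0.0
    cut_profile: pd.DataFrame | None = None
    spike_table: pd.DataFrame | None = None
    tuning: np.ndarray | None = None                 # session-wide (n_cells, 90)
    cell_info: pd.DataFrame | None = None            # acceptance + SI + fields
    locking: pd.DataFrame | None = None              # FG/NFG profile
    posteriors: dict = field(default_factory=dict)   # variant -> Posterior
    decoder_info: dict = field(default_factory=dict)
    sequences: pd.DataFrame | None = None
    shift_data: ShiftData | None = None
    shift_nulls: dict = field(default_factory=dict)
    quadrants: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"seed": self.seed, "n_laps": len(self.laps),
               "cut_phase_deg": self.cut_phase_deg}
        if self.locking is not None and len(self.locking):
            labels = self.locking["label"]
            out["n_fg"] = int((labels == "FG").sum())
            out["n_nfg"] = int((labels == "NFG").sum())
            out["n_unclassified"] = int((labels == "unclassified").sum())
            n_cls = out["n_fg"] + out["n_nfg"]
            out["fg_fraction"] = out["n_fg"] / n_cls if n_cls else None
        if self.sequences is not None and len(self.sequences):
            seqs = self.sequences
            out["n_sequences"] = int(len(seqs))
            for var in ("raw", "exfg", "exnfg"):
                col = f"corr_{var}"
                if col in seqs:
                    out[f"mean_corr_{var}"] = float(np.nanmean(seqs[col]))
                    per_lap = seqs.groupby("lap")[col].mean()
                    out[f"corr_{var}_by_lap"] = {int(k): float(v)
                                                 for k, v in per_lap.items()}
        for key, res in self.shift_nulls.items():
            out[f"shift_{key}"] = {"observed": res["observed"],
                                   "ci95": list(res["ci95"]),
                                   "p_left": res["p_left"],
                                   "n_records": res["n_records"]}
        for key, q in self.quadrants.items():
            out[f"quadrants_{key}"] = {"Q1": q["quadrants"]["Q1"],
                                       "p_q1": q["p_q1"],
                                       "n_sequences": q["n_sequences"]}
        out["dropped"] = self.dropped
        return out


def running_intervals(t, speed, laps, speed_min, min_duration=0.1):
    """Within-lap intervals where speed exceeds the locomotion filter."""
    t = np.asarray(t, float)
    speed = np.asarray(speed, float)
    out = []
    for a, b in laps:
        m = (t >= a) & (t < b)
        idx = np.nonzero(m)[0]
        if idx.size == 0:
            continue
        run = speed[idx] > speed_min
        d = np.diff(run.astype(int))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0] + 1)
        if run[0]:
            starts = [0] + starts
        if run[-1]:
            ends = ends + [run.size]
        dt = t[1] - t[0]
        for s, e in zip(starts, ends):
            t0 = t[idx[s]]
            t1 = min(t[idx[e - 1]] + dt, b)
            if t1 - t0 >= min_duration:
                out.append((float(t0), float(t1)))
    return out


def lap_of_time(times, laps):
    lap = np.full(np.asarray(times).shape, -1, dtype=int)
    for i, (a, b) in enumerate(laps):
        lap[(np.asarray(times) >= a) & (np.asarray(times) < b)] = i
    return lap


def tuning_matrix(spikes: pd.DataFrame, n_cells, t_pos, angle_deg, speed,
                  interval=None, speed_min=5.0, n_bins=90):
    """(n_cells, n_bins) rate matrix from locomotion spikes.

    ``interval`` restricts both spikes and occupancy to a time window (a
    single trial); NaN marks unoccupied bins.
    """
    t_pos = np.asarray(t_pos, float)
    m_pos = np.ones(t_pos.size, dtype=bool)
    st_all = spikes["t"].to_numpy()
    sc_all = spikes["cell_id"].to_numpy()
    m_spk = np.ones(st_all.size, dtype=bool)
    if interval is not None:
        a, b = interval
        m_pos = (t_pos >= a) & (t_pos < b)
        m_spk = (st_all >= a) & (st_all < b)
    rates = np.full((n_cells, n_bins), np.nan)
    tp, ang, spd = t_pos[m_pos], np.asarray(angle_deg)[m_pos], np.asarray(speed)[m_pos]
    for cid in range(n_cells):
        st = st_all[m_spk & (sc_all == cid)]
        curve = placecells.compute_tuning_curve(st, tp, ang, spd,
                                                speed_min=speed_min, n_bins=n_bins)
        rates[cid] = curve.rate
    return rates


def analyze_session(session, config: PipelineConfig | None = None, seed=0,
                    n_shuffles=None, do_decoding=True, do_sequences=True,
                    do_precession=True, optimize_cut=None) -> SessionResult:
    """Run the full analysis on one session.

    ``session`` is an in-memory synthetic Session (or any object exposing
    the same fields).  Heavyweight stages can be switched off for partial
    runs; ``n_shuffles`` overrides the config value (e.g. for scaled-down
    nulls).
    """
    cfg = config or PipelineConfig()
    if n_shuffles is None:
        n_shuffles = cfg.n_shuffles
    if optimize_cut is None:
        optimize_cut = cfg.optimize_cut
    master = np.random.SeedSequence([int(seed), 917])
    sub = master.spawn(4)
    res = SessionResult(config=cfg, seed=int(seed), laps=list(session.laps))

    # ---- behavior -------------------------------------------------------
    pos = session.position
    speed = placecells.estimate_speed(pos.t, pos.x, pos.y)
    angle = placecells.track_angle(pos.x, pos.y)
    ang_unw = np.rad2deg(np.unwrap(np.deg2rad(angle)))
    direction = 1 if np.nanmedian(np.diff(ang_unw)) >= 0 else -1
    res.kin = {"t": pos.t, "speed": speed, "angle_deg": angle,
               "angle_unwrapped_deg": ang_unw, "direction": direction}

    # ---- signals --------------------------------------------------------
    lfp = session.lfp.lfp
    fs = session.lfp.fs
    t_lfp = session.lfp.t
    theta_f = bandpass(lfp, fs, cfg.theta_band)
    slow_f = bandpass(lfp, fs, cfg.slow_gamma_band)
    fast_f = bandpass(lfp, fs, cfg.fast_gamma_band)
    res.phases = {
        "theta": instantaneous_phase(theta_f),
        "slow": instantaneous_phase(slow_f),
        "fast": instantaneous_phase(fast_f),
    }
    p_slow = morlet_band_power(lfp, fs, cfg.slow_gamma_band, n_cycles=cfg.wavelet_cycles)
    p_fast = morlet_band_power(lfp, fs, cfg.fast_gamma_band, n_cycles=cfg.wavelet_cycles)
    res.z_power = {
        "slow": zscore_in_intervals(t_lfp, p_slow, session.laps),
        "fast": zscore_in_intervals(t_lfp, p_fast, session.laps),
    }
    res.episodes = detect_gamma_episodes(t_lfp, res.z_power["slow"],
                                         res.z_power["fast"],
                                         threshold=cfg.episode_z,
                                         window_ms=cfg.episode_window_ms)

    # ---- spike phases and cell pools ------------------------------------
    res.spike_table = assign_spike_phases(
        session.spikes, t_lfp, res.phases, session.laps,
        speed_t=pos.t, speed=speed, episodes=res.episodes)
    n_cells = int(session.spikes["cell_id"].max()) + 1 if len(session.spikes) else 0
    if hasattr(session, "cells") and session.cells is not None:
        n_cells = max(n_cells, len(session.cells))
    res.tuning = tuning_matrix(session.spikes, n_cells, pos.t, angle, speed,
                               speed_min=cfg.speed_min, n_bins=cfg.n_pos_bins)
    # occupancy for SI/fields comes from one empty-spike curve (shared)
    occ_curve = placecells.compute_tuning_curve(
        np.array([]), pos.t, angle, speed, speed_min=cfg.speed_min,
        n_bins=cfg.n_pos_bins)
    cell_rows = []
    for cid in range(n_cells):
        curve = placecells.TuningCurve(rate=res.tuning[cid],
                                       occupancy_p=occ_curve.occupancy_p,
                                       occupancy_s=occ_curve.occupancy_s,
                                       n_spikes=int((session.spikes["cell_id"] == cid).sum()))
        fields, accepted = placecells.detect_place_fields(curve)
        try:
            si = placecells.spatial_information(curve)
        except ValueError:
            si, accepted = np.nan, False
        cell_rows.append({
            "cell_id": cid,
            "peak_hz": curve.peak_rate,
            "mean_hz": curve.mean_rate,
            "field_com_deg": fields[0].com_deg if fields else np.nan,
            "field_size_bins": fields[0].size_bins if fields else 0,
            "si_bits": si,
            "accepted": accepted,
        })
    res.cell_info = pd.DataFrame(cell_rows).set_index("cell_id")
    res.locking = classify_cells(res.spike_table, n_laps=len(session.laps),
                                 alpha=cfg.fg_alpha,
                                 min_spikes_per_lap=cfg.min_spikes_per_lap,
                                 speed_min=cfg.speed_min)
    res.locking = res.locking.reindex(range(n_cells))
    res.locking["label"] = res.locking["label"].fillna("unclassified")

    accepted_cells = res.cell_info.index[res.cell_info["accepted"]].to_numpy()
    fg_cells = res.locking.index[(res.locking["label"] == "FG")
                                 & res.cell_info["accepted"]].to_numpy()
    nfg_cells = res.locking.index[(res.locking["label"] == "NFG")
                                  & res.cell_info["accepted"]].to_numpy()

    if not do_decoding:
        if do_precession:
            cycles = segment_theta_cycles(t_lfp, res.phases["theta"], cut_phase_deg=0.0)
            flag_slow_gamma_event_cycles(cycles, t_lfp, res.z_power["slow"],
                                         threshold=cfg.event_z)
            res.cycles = cycles
            troughs = sg_trough_times(t_lfp, res.phases["slow"])
            res.shift_data = build_shift_data(
                res.spike_table, cycles, troughs, cell_labels=res.locking["label"],
                accepted_cells=accepted_cells, restrict_to_events=True)
            if len(res.shift_data) and n_shuffles:
                shuffle_seed = int(sub[1].generate_state(1)[0] % (2**31))
                res.shift_nulls["all"] = shuffle_null(
                    res.shift_data, n_shuffles=n_shuffles, seed=shuffle_seed,
                    level="sequence")
        return res

    # ---- per-trial Bayesian decoding ------------------------------------
    fg_mask = np.isin(np.arange(n_cells), fg_cells)
    nfg_mask = np.isin(np.arange(n_cells), nfg_cells)
    spike_counts = np.bincount(session.spikes["cell_id"].to_numpy(), minlength=n_cells)
    variants = {"raw": None}
    exclusion_ok = fg_mask.any() and nfg_mask.any() and nfg_mask.sum() >= fg_mask.sum()
    if exclusion_ok:
        variants.update({"exfg": None, "exnfg": None})
    st_by_cell = [session.spikes.loc[session.spikes["cell_id"] == cid, "t"].to_numpy()
                  for cid in range(n_cells)]
    run_ints_all = running_intervals(pos.t, speed, session.laps, cfg.speed_min)
    posts = {v: [] for v in variants}
    angle_fn = lambda tt: np.interp(tt, pos.t, ang_unw) % 360.0  # noqa: E731
    ds_seed = int(sub[0].generate_state(1)[0] % (2**31))
    for lap, (a, b) in enumerate(session.laps):
        lap_rates = tuning_matrix(session.spikes, n_cells, pos.t, angle, speed,
                                  interval=(a, b), speed_min=cfg.speed_min,
                                  n_bins=cfg.n_pos_bins)
        if exclusion_ok:
            decs, info = make_exclusion_decoders(
                lap_rates, np.arange(n_cells), fg_mask, nfg_mask,
                seed=ds_seed, spike_counts=spike_counts,
                tau=cfg.decode_window_s, rate_floor=cfg.rate_floor_hz)
            if lap == 0:
                res.decoder_info = info
        else:
            decs = {"raw": build_decoder(lap_rates, np.arange(n_cells),
                                         tau=cfg.decode_window_s,
                                         rate_floor=cfg.rate_floor_hz)}
        lap_ints = [iv for iv in run_ints_all if a <= iv[0] < b]
        for v in variants:
            v_spikes = [st_by_cell[int(c)] for c in decs[v].cell_ids]
            posts[v].append(decode_session(decs[v], v_spikes, lap_ints,
                                           width=cfg.decode_window_s,
                                           step=cfg.decode_step_s,
                                           true_angle_fn=angle_fn))
    for v in variants:
        parts = [p for p in posts[v] if p.centers.size]
        if parts:
            res.posteriors[v] = Posterior(
                centers=np.concatenate([p.centers for p in parts]),
                P=np.vstack([p.P for p in parts]),
                n_spikes=np.concatenate([p.n_spikes for p in parts]),
                true_angle_deg=np.concatenate([p.true_angle_deg for p in parts]))
        else:
            res.posteriors[v] = Posterior(centers=np.array([]),
                                          P=np.zeros((0, cfg.n_pos_bins)),
                                          n_spikes=np.array([], dtype=int))

    if not do_sequences:
        return res

    # ---- theta cycles, cutting phase, sequences -------------------------
    ctx = SequenceContext(pos_t=pos.t, angle_unwrapped_deg=ang_unw, speed=speed,
                          accepted_cells=accepted_cells, config=cfg,
                          direction_sign=direction)
    spike_df = res.spike_table.rename(columns={"t": "t"})
    cut = 0.0
    if optimize_cut:
        try:
            cut, res.cut_profile = optimize_cut_phase(
                t_lfp, res.phases["theta"], res.posteriors["raw"], spike_df, ctx)
        except ValueError:
            cut = 0.0
    res.cut_phase_deg = cut
    cycles = segment_theta_cycles(t_lfp, res.phases["theta"], cut_phase_deg=cut)
    flag_slow_gamma_event_cycles(cycles, t_lfp, res.z_power["slow"],
                                 threshold=cfg.event_z)
    res.cycles = cycles
    seqs = detect_sequences(cycles, res.posteriors, spike_df, ctx)
    if len(seqs):
        seqs["lap"] = lap_of_time(seqs["t_mid"].to_numpy(), session.laps)
    res.sequences = seqs
    res.dropped["sequences"] = seqs.attrs.get("n_dropped", {})

    if not do_precession or not len(seqs):
        return res

    # ---- slow-gamma phase precession ------------------------------------
    troughs = sg_trough_times(t_lfp, res.phases["slow"])
    labels = res.locking["label"]
    res.shift_data = build_shift_data(
        spike_df, cycles, troughs, cell_labels=labels,
        accepted_cells=accepted_cells, restrict_to_events=True)
    # dominance labels per sequence
    st_idx = np.searchsorted(troughs, spike_df["t"].to_numpy(), side="right") - 1
    dom = [label_sequence_dominance(row, spike_df, st_idx, fg_cells,
                                    accepted_cells)
           for _, row in seqs.iterrows()]
    seqs["dominance"] = dom
    event_by_cycle = dict(zip(range(len(cycles)), cycles.is_slow_gamma_event))
    seqs["sg_event"] = [bool(event_by_cycle.get(c, False)) for c in seqs["cycle_id"]]

    shuffle_seed = int(sub[1].generate_state(1)[0] % (2**31))
    if len(res.shift_data):
        res.shift_nulls["all"] = shuffle_null(res.shift_data, n_shuffles=n_shuffles,
                                              seed=shuffle_seed, level="sequence")
    q_seed = int(sub[2].generate_state(1)[0] % (2**31))
    for stratum in ("FG", "NFG"):
        sel = seqs[seqs["dominance"] == stratum]
        if len(sel) >= 10 and len(res.shift_data):
            res.quadrants[stratum] = quadrant_analysis(
                res.shift_data, sel, corr_col="corr_raw",
                n_shuffles=n_shuffles, seed=q_seed)
    return res


def run_pipeline(session, config: PipelineConfig | None = None, seed=0,
                 out_dir=None, **kwargs) -> SessionResult:
    """Analyze a session and optionally write the result tables.

    ``session`` may be a Session object or a session directory path (which
    is read and minimally adapted).
    """
    if isinstance(session, (str, Path)):
        from .session_io import read_session
        from .synthetic import PositionTrack, LfpGroundTruth, Session as Sess
        loaded = read_session(session)
        t = loaded.position["t_s"].to_numpy()
        x = loaded.position["x_cm"].to_numpy()
        y = loaded.position["y_cm"].to_numpy()
        angle = placecells.track_angle(x, y)
        ang_unw = np.rad2deg(np.unwrap(np.deg2rad(angle)))
        pos = PositionTrack(t=t, x=x, y=y, angle_unwrapped_deg=ang_unw,
                            speed_true=np.full(t.size, np.nan), laps=loaded.laps)
        lfp = LfpGroundTruth(t=loaded.lfp_t, fs=loaded.lfp_fs, lfp=loaded.lfp,
                             theta_phase_deg=np.array([]),
                             sg_phase_unwrapped_deg=np.array([]),
                             fg_phase_unwrapped_deg=np.array([]),
                             bursts=pd.DataFrame())
        spikes = loaded.spikes.rename(columns={"t_s": "t"})
        session = Sess(config=None, position=pos, lfp=lfp, spikes=spikes, cells=None)
    res = analyze_session(session, config=config, seed=seed, **kwargs)
    if out_dir is not None:
        write_results(res, out_dir)
    return res


def write_results(res: SessionResult, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if res.episodes:
        pd.DataFrame([vars(e) for e in res.episodes]).to_csv(
            out / "episodes.csv", index=False)
    if res.cycles is not None and len(res.cycles):
        pd.DataFrame({
            "cycle_id": np.arange(len(res.cycles)),
            "t_start_s": res.cycles.t_start, "t_end_s": res.cycles.t_end,
            "valid": res.cycles.valid,
            "mean_z_slow": res.cycles.mean_z_slow,
            "is_event": res.cycles.is_slow_gamma_event,
        }).to_csv(out / "cycles.csv", index=False)
    if res.cell_info is not None:
        res.cell_info.to_csv(out / "cells.csv")
    if res.locking is not None:
        res.locking.to_csv(out / "locking.csv")
    if res.sequences is not None and len(res.sequences):
        res.sequences.to_csv(out / "sequences.csv", index=False)
    if res.shift_data is not None:
        res.shift_data.records.to_csv(out / "phase_shift.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(res.summary()), fh, indent=2, sort_keys=True)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
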