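"""Ground-truth synthetic sessions: position, LFP, and place-cell spikes.

The generator emulates the study design the analysis pipeline assumes: a
rat running unidirectional laps on a 90-cm circular track with rest-box
pauses between laps, an LFP with 8 Hz theta and nested slow (25-45 Hz) and
fast (65-100 Hz) gamma bursts at fixed theta phases, and place cells firing
as inhomogeneous Poisson processes.

Forward model for spikes
------------------------
Each cell has a von-Mises spatial envelope.  The envelope is evaluated at a
*represented* position: the animal's true position plus a within-theta-cycle
sawtooth sweep running from ``-sweep_half_span_cm`` behind the animal at the
cycle start (theta trough) to the same distance ahead at the cycle end.
This single mechanism produces both theta phase precession (a cell is first
entered by the sweep late in the cycle, and exits it early) and forward
theta sequences (at any moment the active ensemble encodes the swept
position).  Fast-gamma-locked cells get a multiplicative von Mises gain on
the ground-truth fast-gamma phase.  Slow-gamma phase precession is a second
multiplicative von Mises gain whose preferred slow-gamma phase advances by
the configured slope per successive slow-gamma cycle within each theta
cycle, so the spikes a cell emits in adjacent slow-gamma cycles advance in
phase by that slope on average.  Both gains are normalized to leave the
mean rate unchanged, and the slow- and fast-gamma oscillators drift
independently, so the injections do not interfere.

Every output is reproducible bit-for-bit from ``(config, seed)``; per-cell
spike streams use independent substreams of the master seed so cell
ordering cannot perturb other cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import i0

from .config import SimConfig


@dataclass
class PositionTrack:
    t: np.ndarray            # s, at pos_fs
    x: np.ndarray            # cm
    y: np.ndarray            # cm
    angle_unwrapped_deg: np.ndarray  # cumulative track angle (360 per lap)
    speed_true: np.ndarray   # cm/s
    laps: list               # [(t_start, t_end)] per lap

    @property
    def angle_deg(self):
        return self.angle_unwrapped_deg % 360.0

    @property
    def duration(self):
        return float(self.t[-1])


@dataclass
class LfpGroundTruth:
    t: np.ndarray
    fs: float
    lfp: np.ndarray                    # uV
    theta_phase_deg: np.ndarray        # trough-zero, wrapped [0, 360)
    sg_phase_unwrapped_deg: np.ndarray
    fg_phase_unwrapped_deg: np.ndarray
    bursts: pd.DataFrame               # rhythm, t_center, t_start, t_end, amp_scale

    @property
    def sg_phase_deg(self):
        return self.sg_phase_unwrapped_deg % 360.0

    @property
    def fg_phase_deg(self):
        return self.fg_phase_unwrapped_deg % 360.0


@dataclass
class Session:
    """One synthetic recording session with its ground truth."""

    config: SimConfig
    position: PositionTrack
    lfp: LfpGroundTruth
    spikes: pd.DataFrame     # cell_id, t
    cells: pd.DataFrame      # cell_id, is_fg, center_deg, ...

    @property
    def laps(self):
        return self.position.laps


def _rng(seed, *key):
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def generate_position(config: SimConfig, seed=None) -> PositionTrack:
    """Simulate unidirectional laps on the circular track.

    Speed is drawn per position sample from a clipped normal distribution
    (smoothed over ~0.5 s so it changes on behavioral timescales), the
    animal rests at the track origin (the rest box) between laps, and lap
    boundaries are recorded at the samples where the cumulative angle
    crosses multiples of 360 degrees.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 0)
    r = config.track_radius
    dt = 1.0 / config.pos_fs
    if dt <= 0 or config.run_speed_mean <= 0:
        raise ValueError("non-positive duration or sampling rate")

    speeds = []
    angles = []  # unwrapped, deg
    lap_bounds = []
    angle = 0.0
    t_idx = 0

    def rest(n):
        nonlocal t_idx, angle
        for _ in range(n):
            speeds.append(0.0)
            angles.append(angle)
            t_idx += 1

    rest(int(round(config.lead_in_s * config.pos_fs)))
    for lap in range(config.n_laps):
        lap_start = t_idx * dt
        target = 360.0 * (lap + 1)
        # draw a generous speed series for this lap and smooth it
        n_guess = int(np.ceil((2 * np.pi * r / max(config.run_speed_mean, 1e-9))
                              / dt * 4)) + 50
        v = rng.normal(config.run_speed_mean, config.run_speed_sd, size=n_guess)
        if config.run_speed_sd > 0:
            kernel = np.hanning(13)
            kernel /= kernel.sum()
            # smoothing shrinks the SD; rescale to keep the configured spread
            v = config.run_speed_mean + (np.convolve(v, kernel, mode="same")
                                         - config.run_speed_mean) * 3.0
        v = np.clip(v, 0.0, None)
        i = 0
        while angle < target:
            if i >= v.size:  # extremely slow draw; extend
                v = np.concatenate([v, np.full(1000, config.run_speed_mean)])
            speeds.append(float(v[i]))
            angle += np.rad2deg(v[i] / r) * dt
            angles.append(angle)
            t_idx += 1
            i += 1
        angle = target  # snap to the lap boundary; the rest box sits at 0 deg
        angles[-1] = target
        lap_bounds.append((lap_start, t_idx * dt))
        rest(int(round(config.rest_duration_s * config.pos_fs)))

    t = np.arange(len(angles)) * dt
    ang = np.asarray(angles)
    x = r * np.cos(np.deg2rad(ang))
    y = r * np.sin(np.deg2rad(ang))
    return PositionTrack(t=t, x=x, y=y, angle_unwrapped_deg=ang,
                         speed_true=np.asarray(speeds), laps=lap_bounds)


def _drifting_phase(rng, f0, jitter_sd, n, fs):
    """Unwrapped phase (deg) of an oscillator with slow frequency drift."""
    if jitter_sd > 0:
        # AR(1) drift with ~0.15 s correlation time
        alpha = np.exp(-1.0 / (0.15 * fs))
        white = rng.normal(0.0, jitter_sd * np.sqrt(1 - alpha**2), size=n)
        drift = sps.lfilter([1.0], [1.0, -alpha], white)
    else:
        drift = np.zeros(n)
    f_inst = np.clip(f0 + drift, 0.3 * f0, None)
    phase0 = rng.uniform(0.0, 360.0)
    return phase0 + 360.0 * np.cumsum(f_inst) / fs


def _burst_envelope(t, centers, widths, amps):
    """Sum of Hann bumps (peak ``amp``) at the given centers/full widths."""
    env = np.zeros(t.size)
    fs = 1.0 / (t[1] - t[0])
    for c, w, a in zip(centers, widths, amps):
        i0_ = max(int((c - w / 2 - t[0]) * fs), 0)
        i1_ = min(int((c + w / 2 - t[0]) * fs) + 1, t.size)
        if i1_ <= i0_:
            continue
        tt = t[i0_:i1_]
        env[i0_:i1_] += a * 0.5 * (1 + np.cos(2 * np.pi * (tt - c) / w))
    return env


def synthesize_lfp(position: PositionTrack, config: SimConfig, seed=None) -> LfpGroundTruth:
    """Compose the LFP: theta + amplitude-modulated gamma bursts + noise.

    The trough of every rhythm corresponds to ground-truth phase 0.  Gamma
    bursts are placed at a fixed theta phase per rhythm (slow gamma on the
    descending phase, fast gamma near the trough by default), only during
    laps, with Hann envelopes whose peak amplitude is drawn per burst as a
    multiple of the baseline gamma amplitude.  Strong bursts are constructed
    to push the z-scored band power above the episode threshold.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 1)
    fs = config.lfp_fs
    n = int(round(position.duration * fs)) + 1
    t = np.arange(n) / fs

    theta_phase = (360.0 * config.theta_freq * t)  # unwrapped, trough-zero
    lfp = config.theta_amp_uv * (-np.cos(np.deg2rad(theta_phase)))

    sg_phase = _drifting_phase(rng, config.slow_gamma_freq,
                               config.sg_freq_jitter_hz, n, fs)
    fg_phase = _drifting_phase(rng, config.fast_gamma_freq,
                               config.fg_freq_jitter_hz, n, fs)

    cycle_dur = 1.0 / config.theta_freq
    in_lap = np.zeros(n, dtype=bool)
    for t0, t1 in position.laps:
        in_lap[(t >= t0) & (t < t1)] = True

    burst_rows = []
    envs = {}
    for rhythm, prob, scale_rng, phase_c, duty, base in (
        ("slow", config.sg_burst_prob, config.sg_burst_amp_scale,
         config.sg_burst_theta_phase, config.sg_burst_duty, config.sg_base_amp_uv),
        ("fast", config.fg_burst_prob, config.fg_burst_amp_scale,
         config.fg_burst_theta_phase, config.fg_burst_duty, config.fg_base_amp_uv),
    ):
        n_cycles = int(theta_phase[-1] // 360.0)
        centers, widths, amps, scales = [], [], [], []
        for k in range(n_cycles):
            # time at which theta phase hits the burst center phase in cycle k
            c = (k + (phase_c % 360.0) / 360.0) * cycle_dur
            idx = int(c * fs)
            if idx >= n or not in_lap[idx]:
                continue
            if rng.uniform() >= prob:
                continue
            s = rng.uniform(*scale_rng)
            centers.append(c)
            widths.append(duty * cycle_dur)
            amps.append(s * base)
            scales.append(s)
        env = _burst_envelope(t, centers, widths, amps)
        envs[rhythm] = env
        for c, w, s in zip(centers, widths, scales):
            burst_rows.append({"rhythm": rhythm, "t_center": c,
                               "t_start": c - w / 2, "t_end": c + w / 2,
                               "amp_scale": s})

    lfp += (config.sg_base_amp_uv + envs["slow"]) * (-np.cos(np.deg2rad(sg_phase)))
    lfp += (config.fg_base_amp_uv + envs["fast"]) * (-np.cos(np.deg2rad(fg_phase)))
    lfp += rng.normal(0.0, config.noise_amp_uv, size=n)

    bursts = pd.DataFrame(burst_rows,
                          columns=["rhythm", "t_center", "t_start", "t_end", "amp_scale"])
    return LfpGroundTruth(t=t, fs=fs, lfp=lfp,
                          theta_phase_deg=theta_phase % 360.0,
                          sg_phase_unwrapped_deg=sg_phase,
                          fg_phase_unwrapped_deg=fg_phase,
                          bursts=bursts)


def _field_kappa(field_width_deg):
    # exp(kappa (cos(w/2) - 1)) = 0.1 at the 10%-of-peak field edge
    half = np.deg2rad(field_width_deg / 2.0)
    return np.log(10.0) / (1.0 - np.cos(half))


def generate_spikes(position: PositionTrack, lfp: LfpGroundTruth,
                    config: SimConfig, seed=None):
    """Inhomogeneous-Poisson spikes for every cell, plus per-cell truth.

    Returns ``(spikes, cells)``: a DataFrame of (cell_id, t) and a
    DataFrame of per-cell ground truth (FG flag, field center, locking and
    precession parameters).  Thinning runs per LFP sample on an independent
    substream per cell.
    """
    if seed is None:
        seed = config.seed
    fs = lfp.fs
    t = lfp.t
    n = t.size
    dt = 1.0 / fs
    if abs(position.duration - t[-1]) > 1.0:
        raise ValueError("position and LFP clocks are misaligned")

    # behavior interpolated onto the LFP clock
    ang_u = np.interp(t, position.t, position.angle_unwrapped_deg)
    speed = np.interp(t, position.t, position.speed_true)
    theta_frac = (lfp.theta_phase_deg % 360.0) / 360.0

    r = config.track_radius
    sweep_deg = np.rad2deg(config.sweep_half_span_cm / r)
    sweep = sweep_deg * (2.0 * theta_frac - 1.0)

    rng_master = _rng(seed, 2)
    n_fg = int(round(config.fg_fraction * config.n_cells))
    fg_ids = rng_master.choice(config.n_cells, size=n_fg, replace=False)
    is_fg = np.zeros(config.n_cells, dtype=bool)
    is_fg[fg_ids] = True
    jitter = rng_master.uniform(-2.0, 2.0, size=config.n_cells)
    centers = (np.arange(config.n_cells) + 0.5) * 360.0 / config.n_cells + jitter

    kappa_s = _field_kappa(config.field_width)
    fg_gain_norm = i0(config.fg_kappa)
    sg_gain_norm = i0(config.sg_phase_kappa)

    # slow-gamma cycle ordinal within each theta cycle (0 at the first
    # trough of the cycle), used to advance the preferred slow-gamma phase
    sg_cycle_idx = np.floor(lfp.sg_phase_unwrapped_deg / 360.0).astype(np.int64)
    theta_cycle_idx = np.floor(config.theta_freq * t).astype(np.int64)
    n_theta = int(theta_cycle_idx[-1]) + 1
    first_sample = np.searchsorted(theta_cycle_idx, np.arange(n_theta), side="left")
    sg_at_theta_start = sg_cycle_idx[np.clip(first_sample, 0, n - 1)]
    sg_ordinal = sg_cycle_idx - sg_at_theta_start[theta_cycle_idx]

    lap_of_sample = np.full(n, -1, dtype=np.int64)
    for lap, (t0, t1) in enumerate(position.laps):
        lap_of_sample[(t >= t0) & (t < t1)] = lap

    sg_phase_wrapped = lfp.sg_phase_unwrapped_deg % 360.0
    rows_t = []
    rows_id = []
    for cid in range(config.n_cells):
        rng = _rng(seed, 3, cid)
        use_sweep = (not config.sweep_fg_only) or is_fg[cid]
        rep = ang_u + (sweep if use_sweep else 0.0)
        delta = np.deg2rad(rep - centers[cid])
        rate = config.peak_rate * np.exp(kappa_s * (np.cos(delta) - 1.0))
        if is_fg[cid] and config.fg_kappa > 0:
            gain = np.exp(config.fg_kappa
                          * np.cos(np.deg2rad(lfp.fg_phase_unwrapped_deg
                                              - config.fg_pref_phase_deg)))
            rate = rate * (gain / fg_gain_norm)
        slopes = np.array([config.sg_slope_for(bool(is_fg[cid]), lap)
                           for lap in range(config.n_laps)])
        if np.any(slopes != 0.0) and config.sg_phase_kappa > 0:
            slope_t = np.where(lap_of_sample >= 0,
                               slopes[np.clip(lap_of_sample, 0, None)], 0.0)
            mu = 180.0 + slope_t * sg_ordinal
            sg_gain = np.exp(config.sg_phase_kappa
                             * np.cos(np.deg2rad(sg_phase_wrapped - mu)))
            sg_gain /= sg_gain_norm
            # laps with zero slope keep an unmodulated rate
            rate = rate * np.where(slope_t != 0.0, sg_gain, 1.0)
        rate = rate + config.noise_rate
        counts = rng.poisson(rate * dt)
        spikes_mask = counts > 0
        reps = counts[spikes_mask]
        st = np.repeat(t[spikes_mask], reps)
        if st.size == 0:
            continue
        rows_t.append(st)
        rows_id.append(np.full(st.size, cid))

    if rows_t:
        spikes = pd.DataFrame({
            "cell_id": np.concatenate(rows_id),
            "t": np.concatenate(rows_t),
        }).sort_values(["t", "cell_id"], kind="mergesort").reset_index(drop=True)
    else:
        spikes = pd.DataFrame({"cell_id": np.array([], dtype=int),
                               "t": np.array([], dtype=float)})

    cells = pd.DataFrame({
        "cell_id": np.arange(config.n_cells),
        "is_fg": is_fg,
        "center_deg": centers % 360.0,
        "fg_kappa": np.where(is_fg, config.fg_kappa, 0.0),
        "fg_pref_deg": np.where(is_fg, config.fg_pref_phase_deg, np.nan),
        "carries_sweep": np.where(config.sweep_fg_only, is_fg, True).astype(bool),
    })
    return spikes, cells


def simulate_session(config: SimConfig, seed=None) -> Session:
    """Generate a full session (position, LFP, spikes) from one seed."""
    if seed is None:
        seed = config.seed
    pos = generate_position(config, seed)
    lfp = synthesize_lfp(pos, config, seed)
    spikes, cells = generate_spikes(pos, lfp, config, seed)
    return Session(config=config, position=pos, lfp=lfp, spikes=spikes, cells=cells)
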