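"""Configuration objects for the simulator and the analysis pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic recording session.

    The defaults describe one session of the study design the analyses
    assume: a rat running unidirectional laps on a circular track (90 cm
    inner diameter), CA1-like LFP at 2000 Hz containing 8 Hz theta with
    nested 25-45 Hz and 65-100 Hz gamma bursts, and place cells with
    von-Mises angular tuning whose within-theta-cycle firing sweeps from
    behind to ahead of the animal (which is what produces theta phase
    precession and theta sequences).  A configurable subset of cells is
    phase-locked to fast gamma, and spikes can carry slow-gamma phase
    precession at a set number of degrees per slow-gamma cycle.
    """

    # track and behavior
    track_inner_diameter: float = 90.0   # cm; running radius = diameter / 2
    n_laps: int = 5
    run_speed_mean: float = 25.0         # cm/s
    run_speed_sd: float = 3.0            # cm/s
    rest_duration_s: float = 4.0         # zero-speed gap between laps (rest box)
    lead_in_s: float = 2.0               # rest before the first lap

    # sampling and rhythms
    lfp_fs: float = 2000.0               # Hz
    pos_fs: float = 25.0                 # Hz
    theta_freq: float = 8.0              # Hz
    slow_gamma_band: tuple = (25.0, 45.0)
    fast_gamma_band: tuple = (65.0, 100.0)
    slow_gamma_freq: float = 37.0        # oscillator center frequency, Hz
    fast_gamma_freq: float = 81.0
    sg_freq_jitter_hz: float = 4.0       # SD of slow-gamma frequency drift
    fg_freq_jitter_hz: float = 14.0      # SD of fast-gamma frequency drift

    # LFP amplitudes (uV) and burst structure
    theta_amp_uv: float = 200.0
    sg_base_amp_uv: float = 30.0
    fg_base_amp_uv: float = 25.0
    sg_burst_prob: float = 0.2           # per theta cycle
    fg_burst_prob: float = 0.2
    sg_burst_amp_scale: tuple = (4.0, 7.0)   # envelope peak, multiples of base amp
    fg_burst_amp_scale: tuple = (4.0, 7.0)
    sg_burst_theta_phase: float = 250.0  # descending theta phase (trough = 0)
    fg_burst_theta_phase: float = 20.0   # near the trough
    sg_burst_duty: float = 0.9           # envelope span, fraction of a theta cycle
    fg_burst_duty: float = 0.35
    noise_amp_uv: float = 50.0

    # place cells
    n_cells: int = 45
    peak_rate: float = 35.0              # Hz at the field center
    field_width: float = 72.0            # deg, full width at 10% of peak
    noise_rate: float = 0.1              # Hz baseline, space-independent
    sweep_half_span_cm: float = 20.0     # within-cycle represented-position sweep
    sweep_fg_only: bool = False          # only FG cells carry the sweep structure

    # gamma phase coding
    fg_fraction: float = 0.3             # fraction of cells fast-gamma locked
    fg_kappa: float = 0.8                # von Mises concentration of FG locking
    fg_pref_phase_deg: float = 180.0
    sg_precession_slope: float = -60.0   # deg per slow-gamma cycle (negative = precession)
    sg_slope_fg_by_lap: list | None = None   # per-lap override for FG cells
    sg_slope_nfg_by_lap: list | None = None  # per-lap override for NFG cells
    sg_phase_kappa: float = 8.0          # concentration of spike phase about its target

    seed: int = 0

    def __post_init__(self):
        if self.track_inner_diameter <= 0:
            raise ValueError("track diameter must be positive")
        if self.n_laps < 1:
            raise ValueError("need at least one lap")
        if self.lfp_fs <= 0 or self.pos_fs <= 0:
            raise ValueError("sampling rates must be positive")
        if self.slow_gamma_band[1] > self.fast_gamma_band[0]:
            raise ValueError("slow and fast gamma bands must not overlap")
        if not 0.0 <= self.fg_fraction <= 1.0:
            raise ValueError("fg_fraction must lie in [0, 1]")
        for name in ("run_speed_mean", "peak_rate", "noise_rate", "fg_kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sg_slope_fg_by_lap", "sg_slope_nfg_by_lap"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_laps:
                raise ValueError(f"{name} must have one entry per lap")

    @property
    def track_radius(self):
        return self.track_inner_diameter / 2.0

    def sg_slope_for(self, is_fg: bool, lap: int) -> float:
        """Slow-gamma precession slope for a cell class on a given lap."""
        sched = self.sg_slope_fg_by_lap if is_fg else self.sg_slope_nfg_by_lap
        if sched is not None:
            return float(sched[lap])
        return float(self.sg_precession_slope)


@dataclass
class PipelineConfig:
    """Analysis-stage parameters (the study's printed constants)."""

    theta_band: tuple = (4.0, 12.0)
    slow_gamma_band: tuple = (25.0, 45.0)
    fast_gamma_band: tuple = (65.0, 100.0)
    wavelet_cycles: float = 6.0

    episode_z: float = 3.0
    episode_window_ms: float = 160.0
    event_z: float = 1.5

    n_pos_bins: int = 90
    speed_min: float = 5.0               # cm/s locomotion filter

    decode_window_s: float = 0.020
    decode_step_s: float = 0.005
    rate_floor_hz: float = 0.01

    seq_spatial_halfwidth_bins: int = 10  # ~35 cm at ~3.5 cm per bin
    seq_temporal_halfwidth_s: float = 0.030
    seq_min_duration_s: float = 0.100
    seq_max_duration_s: float = 0.200
    seq_min_cells: int = 4                # "more than 3 place cells"
    seq_min_spikes: int = 5
    strict_participation: bool = False    # each cell >= 5 spikes instead of total
    track_start_deg: float = 30.0         # usable track segment (rest box at 0)
    track_end_deg: float = 330.0

    fg_alpha: float = 0.05
    min_spikes_per_lap: int = 10

    cut_phase_step_deg: float = 10.0
    optimize_cut: bool = True
    min_sequences_for_cut: int = 20

    n_shuffles: int = 1000

    def __post_init__(self):
        if self.episode_z <= 0 or self.event_z <= 0:
            raise ValueError("z thresholds must be positive")
        if self.seq_min_duration_s >= self.seq_max_duration_s:
            raise ValueError("invalid sequence duration bounds")


def load_yaml(path, cls):
    """Load a config dataclass from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in data.items():
        if isinstance(val, list) and isinstance(cls.__dataclass_fields__[key].default, tuple):
            data[key] = tuple(val)
    return cls(**data)


def dump_yaml(cfg, path):
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
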