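"""LFP signal processing: filtering, phase, band power, episodes, cycles.

Phase convention: the trough of an oscillation maps to 0/360 degrees and
the peak to 180 degrees, matching the trough-zero convention used for the
slow-gamma phase-shift analyses.  All filtering is zero-phase
(forward-backward 4th-order Butterworth) so phase estimates are not
delayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


def bandpass(x, fs, band_hz, order=4):
    """Zero-phase Butterworth band-pass filter.

    Parameters
    ----------
    x : array
        Voltage trace.
    fs : float
        Sampling rate (Hz); must exceed twice the band's upper edge.
    band_hz : (low, high)
        Pass band in Hz.
    """
    lo, hi = band_hz
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band_hz}")
    if hi >= fs / 2:
        raise ValueError(f"band {band_hz} exceeds Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def instantaneous_phase(filtered):
    """Hilbert-transform phase with the trough at 0 degrees.

    Returns degrees in ``[0, 360)``.  The analytic-signal angle is 0 at a
    local maximum of the input, so a 180-degree shift places the trough at
    0 and the peak at 180.
    """
    x = np.asarray(filtered, dtype=float)
    if not np.any(x):
        raise ValueError("all-zero trace has undefined phase")
    ang = np.angle(sps.hilbert(x), deg=True)
    return (ang + 180.0) % 360.0


def morlet_band_power(x, fs, band_hz, n_cycles=6.0, freq_step=1.0):
    """Time-varying band power from a complex Morlet wavelet transform.

    Power is computed at ``freq_step``-spaced center frequencies spanning
    the band (edges included) and averaged across frequencies.  The mother
    wavelet has ``n_cycles`` cycles (sigma_t = n_cycles / (2 pi f)) and is
    L2-normalized.

    Returns
    -------
    power : array, same length as ``x`` (arbitrary units)
    """
    x = np.asarray(x, dtype=float)
    lo, hi = band_hz
    freqs = np.arange(lo, hi + 0.5 * freq_step, freq_step)
    acc = np.zeros(x.size)
    for f in freqs:
        sigma_t = n_cycles / (2.0 * np.pi * f)
        half = int(np.ceil(5.0 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        w = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
        conv = sps.oaconvolve(x, w, mode="same")
        acc += np.abs(conv) ** 2
    return acc / freqs.size


def zscore_in_intervals(t, x, intervals):
    """Z-score ``x`` using only samples inside ``intervals``.

    Mean and SD are computed per interval (a "trial"), and samples outside
    every interval are NaN.  Each interval is ``(t_start, t_end)``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.full(x.shape, np.nan)
    for t0, t1 in intervals:
        m = (t >= t0) & (t < t1)
        if not np.any(m):
            continue
        mu = x[m].mean()
        sd = x[m].std()
        if sd == 0:
            raise ValueError("zero variance inside interval; cannot z-score")
        z[m] = (x[m] - mu) / sd
    return z


@dataclass(frozen=True)
class GammaEpisode:
    """A 160-ms high-power window of one gamma rhythm."""

    rhythm: str          # "slow" or "fast"
    t_center: float      # s
    t_start: float       # s  (t_center - window/2)
    t_end: float         # s  (t_center + window/2)
    peak_z: float


def _local_maxima_above(z, threshold):
    """Indices of strict-left / weak-right local maxima with z >= threshold."""
    z = np.asarray(z, dtype=float)
    zf = np.where(np.isfinite(z), z, -np.inf)
    n = zf.size
    if n == 0:
        return np.array([], dtype=int)
    left = np.empty(n, dtype=bool)
    right = np.empty(n, dtype=bool)
    left[0] = True
    left[1:] = zf[1:] >= zf[:-1]
    right[-1] = True
    right[:-1] = zf[:-1] > zf[1:]
    return np.nonzero(left & right & (zf >= threshold))[0]


def detect_gamma_episodes(t, z_slow, z_fast, threshold=3.0, window_ms=160.0):
    """Detect slow- and fast-gamma episodes from z-scored band power.

    A candidate center is a local maximum of z-scored power at or above
    ``threshold``; each defines a ``window_ms`` window.  Overlapping
    candidate windows are resolved greedily by descending peak z (the lower
    amplitude one is discarded), across both rhythms.  Finally a slow
    episode whose window contains fast z >= threshold is removed, and vice
    versa, so the surviving episodes of the two rhythms are mutually
    exclusive in time.
    """
    t = np.asarray(t, dtype=float)
    half = window_ms / 2000.0
    cands = []
    for rhythm, z in (("slow", z_slow), ("fast", z_fast)):
        for i in _local_maxima_above(z, threshold):
            cands.append((float(z[i]), float(t[i]), rhythm))
    # greedy by descending peak z; deterministic tie-break on time then rhythm
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    kept = []
    for z_pk, t_c, rhythm in cands:
        if all(abs(t_c - k[1]) >= 2 * half for k in kept):
            kept.append((z_pk, t_c, rhythm))
    # cross-rhythm exclusion
    z_by = {"slow": np.asarray(z_slow, float), "fast": np.asarray(z_fast, float)}
    episodes = []
    for z_pk, t_c, rhythm in kept:
        other = z_by["fast" if rhythm == "slow" else "slow"]
        m = (t >= t_c - half) & (t <= t_c + half)
        vals = other[m]
        vals = vals[np.isfinite(vals)]
        if vals.size and np.max(vals) >= threshold:
            continue
        episodes.append(GammaEpisode(rhythm=rhythm, t_center=t_c,
                                     t_start=t_c - half, t_end=t_c + half,
                                     peak_z=z_pk))
    episodes.sort(key=lambda e: e.t_center)
    return episodes


@dataclass
class ThetaCycles:
    """Theta cycles as parallel arrays (one entry per cycle).

    ``valid`` flags cycles whose duration lies in the physiological bounds
    implied by the 4-12 Hz band; invalid cycles are excluded from sequence
    detection downstream.
    """

    t_start: np.ndarray
    t_end: np.ndarray
    valid: np.ndarray
    mean_z_slow: np.ndarray = field(default=None)
    is_slow_gamma_event: np.ndarray = field(default=None)

    def __len__(self):
        return self.t_start.size

    @property
    def t_mid(self):
        return 0.5 * (self.t_start + self.t_end)

    @property
    def duration(self):
        return self.t_end - self.t_start


def segment_theta_cycles(t, theta_phase_deg, cut_phase_deg=0.0,
                         min_duration=1.0 / 12.0, max_duration=0.25):
    """Segment a record into theta cycles at a given cutting phase.

    Boundaries are successive upward crossings of ``cut_phase_deg`` in the
    unwrapped phase; crossing times are linearly interpolated between
    samples.  Durations outside ``[min_duration, max_duration]`` seconds
    are flagged invalid (not dropped).
    """
    t = np.asarray(t, dtype=float)
    ph = np.asarray(theta_phase_deg, dtype=float)
    if ph.size == 0:
        return ThetaCycles(t_start=np.array([]), t_end=np.array([]),
                           valid=np.array([], dtype=bool))
    unw = np.unwrap(np.deg2rad(ph))
    unw_deg = np.rad2deg(unw)
    cut = cut_phase_deg % 360.0
    k0 = int(np.ceil((unw_deg[0] - cut) / 360.0))
    k1 = int(np.floor((unw_deg[-1] - cut) / 360.0))
    if k1 < k0:
        return ThetaCycles(t_start=np.array([]), t_end=np.array([]),
                           valid=np.array([], dtype=bool))
    levels = cut + 360.0 * np.arange(k0, k1 + 1)
    # unw_deg is nondecreasing on clean signals but can wiggle with noise;
    # np.interp needs a monotone x, so enforce a running maximum.
    mono = np.maximum.accumulate(unw_deg)
    crossings = np.interp(levels, mono, t)
    if crossings.size < 2:
        return ThetaCycles(t_start=np.array([]), t_end=np.array([]),
                           valid=np.array([], dtype=bool))
    t_start = crossings[:-1]
    t_end = crossings[1:]
    dur = t_end - t_start
    valid = (dur >= min_duration) & (dur <= max_duration)
    return ThetaCycles(t_start=t_start, t_end=t_end, valid=valid)


def flag_slow_gamma_event_cycles(cycles: ThetaCycles, t, z_slow, threshold=1.5):
    """Mark theta cycles whose mean z-scored slow-gamma power >= threshold.

    Fills ``cycles.mean_z_slow`` and ``cycles.is_slow_gamma_event`` in
    place and returns ``cycles``.
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z_slow, dtype=float)
    n = len(cycles)
    mean_z = np.full(n, np.nan)
    i0 = np.searchsorted(t, cycles.t_start, side="left")
    i1 = np.searchsorted(t, cycles.t_end, side="left")
    for i in range(n):
        seg = z[i0[i]:i1[i]]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            mean_z[i] = seg.mean()
    cycles.mean_z_slow = mean_z
    with np.errstate(invalid="ignore"):
        cycles.is_slow_gamma_event = np.where(np.isnan(mean_z), False,
                                              mean_z >= threshold)
    return cycles
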