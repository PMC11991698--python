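"""Behavioral estimators and spatial firing characterization.

Covers running speed and head direction from the position tracker, angular
tuning curves on the circular track (90 bins, ~3.5 cm each), place-field
detection with the standard acceptance criteria (peak rate > 1 Hz, main
field > 3 bins, mean rate <= 15 Hz to exclude putative interneurons), and
the Skaggs spatial-information score in bits per spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_BINS = 90
BIN_DEG = 360.0 / N_BINS


def estimate_speed(t, x, y):
    """Running speed by central differences over flanking position samples.

    ``v_t = dist((x, y)_{t-1}, (x, y)_{t+1}) / (t_{t+1} - t_{t-1})``; at
    25 Hz tracking the elapsed time is 2/25 s.  Endpoints copy the nearest
    interior value.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if t.size < 3:
        raise ValueError("need at least 3 position samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-increasing or duplicate timestamps")
    dt = t[2:] - t[:-2]
    d = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2])
    v = np.empty_like(t)
    v[1:-1] = d / dt
    v[0] = v[1]
    v[-1] = v[-2]
    return v


def estimate_head_direction(t, x, y):
    """Head direction as atan2 of the flanking displacement vector.

    Returned in degrees ``[0, 360)``.  Where the displacement is zero the
    direction is carried forward from the previous sample (and the leading
    run of undefined samples copies the first defined value).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 position samples")
    dx = x[2:] - x[:-2]
    dy = y[2:] - y[:-2]
    d = np.full(n, np.nan)
    moved = (dx != 0) | (dy != 0)
    d[1:-1][moved] = np.rad2deg(np.arctan2(dy[moved], dx[moved])) % 360.0
    # carry forward; endpoints behave like zero-displacement samples
    last = np.nan
    for i in range(n):
        if np.isnan(d[i]):
            d[i] = last
        else:
            last = d[i]
    # leading undefined run: copy first defined value
    if np.isnan(d[0]):
        defined = np.nonzero(~np.isnan(d))[0]
        if defined.size == 0:
            raise ValueError("animal never moved; head direction undefined")
        d[:defined[0]] = d[defined[0]]
    return d


def track_angle(x, y, center=None):
    """Angular position on the circular track, degrees ``[0, 360)``.

    The track center defaults to the midrange of the trajectory extent,
    which (unlike the centroid) is insensitive to uneven dwell times such
    as long rest-box pauses.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if center is None:
        center = ((x.max() + x.min()) / 2.0, (y.max() + y.min()) / 2.0)
    cx, cy = center
    return np.rad2deg(np.arctan2(y - cy, x - cx)) % 360.0


@dataclass
class TuningCurve:
    """Angular firing-rate map over 90 track bins.

    ``rate`` is NaN in bins the animal never occupied (at speed above the
    filter); ``occupancy_p`` sums to 1 over occupied bins.
    """

    rate: np.ndarray         # (90,) Hz, NaN where unoccupied
    occupancy_p: np.ndarray  # (90,)
    occupancy_s: np.ndarray  # (90,) seconds
    n_spikes: int

    @property
    def mean_rate(self):
        occ = self.occupancy_s.sum()
        return float(self.n_spikes / occ) if occ > 0 else np.nan

    @property
    def peak_rate(self):
        return float(np.nanmax(self.rate)) if np.any(np.isfinite(self.rate)) else np.nan


def compute_tuning_curve(spike_times, t_pos, angle_deg, speed, speed_min=5.0,
                         n_bins=N_BINS):
    """Tuning curve from locomotion spikes (running speed > ``speed_min``).

    Occupancy uses the position sampling interval; each spike is assigned
    the angle and speed of the nearest position sample.
    """
    t_pos = np.asarray(t_pos, float)
    angle_deg = np.asarray(angle_deg, float)
    speed = np.asarray(speed, float)
    dt = np.median(np.diff(t_pos))
    run = speed > speed_min
    if not np.any(run):
        raise ValueError("no samples above the speed filter")
    bins = np.clip((angle_deg / (360.0 / n_bins)).astype(int), 0, n_bins - 1)
    occ = np.bincount(bins[run], minlength=n_bins) * dt
    st = np.asarray(spike_times, float)
    idx = np.clip(np.searchsorted(t_pos, st) - 0, 0, t_pos.size - 1)
    # nearest sample
    idx = np.where((idx > 0) & (np.abs(t_pos[np.maximum(idx - 1, 0)] - st)
                                < np.abs(t_pos[idx] - st)), idx - 1, idx)
    keep = run[idx]
    counts = np.bincount(bins[idx[keep]], minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ > 0, counts / occ, np.nan)
    total_occ = occ.sum()
    return TuningCurve(rate=rate, occupancy_p=occ / total_occ, occupancy_s=occ,
                       n_spikes=int(keep.sum()))


@dataclass
class PlaceField:
    bins: np.ndarray        # contiguous (circularly) bin indices
    com_deg: float          # circular center of mass, rate-weighted
    size_bins: int

    @property
    def size_cm(self):
        return self.size_bins * BIN_DEG * np.pi * 90.0 / 360.0  # on 90 cm diameter


def _circular_components(mask):
    """Connected runs of True in a circular boolean array."""
    n = mask.size
    if mask.all():
        return [np.arange(n)]
    comps = []
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return comps
    # break at gaps
    gaps = np.nonzero(np.diff(idx) > 1)[0]
    runs = np.split(idx, gaps + 1)
    # merge wrap-around
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs = runs[:-1]
    return runs


def detect_place_fields(curve: TuningCurve, frac_of_peak=0.1,
                        min_peak_hz=1.0, min_field_bins=3,
                        max_mean_rate_hz=15.0):
    """Place fields and the unit acceptance decision.

    A field is a circularly contiguous run of bins with rate above
    ``frac_of_peak`` of the unit peak; undefined (unoccupied) bins break
    contiguity.  The unit is accepted as a place cell iff its peak exceeds
    ``min_peak_hz``, the main (largest) field spans more than
    ``min_field_bins`` bins, and the mean rate does not exceed
    ``max_mean_rate_hz`` (putative interneuron filter).
    """
    rate = curve.rate
    finite = np.isfinite(rate)
    if not np.any(finite):
        return [], False
    peak = np.nanmax(rate)
    mask = finite & (rate > frac_of_peak * peak)
    fields = []
    for run in _circular_components(mask):
        r = rate[run]
        # circular rate-weighted center of mass
        ang = np.deg2rad(run * BIN_DEG + BIN_DEG / 2.0)
        com = np.rad2deg(np.angle((r * np.exp(1j * ang)).sum())) % 360.0
        fields.append(PlaceField(bins=run, com_deg=float(com), size_bins=run.size))
    fields.sort(key=lambda f: -f.size_bins)
    accepted = (len(fields) > 0
                and peak > min_peak_hz
                and fields[0].size_bins > min_field_bins
                and curve.mean_rate <= max_mean_rate_hz)
    return fields, bool(accepted)


def spatial_information(curve: TuningCurve):
    """Skaggs spatial information in bits per spike.

    ``SI = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda)`` over
    occupied bins, with zero-rate bins contributing 0.  Unoccupied bins are
    excluded after renormalizing the occupancy, which keeps the score
    defined on partial coverage.
    """
    finite = np.isfinite(curve.rate)
    if not np.any(finite):
        raise ValueError("tuning curve has no occupied bins")
    p = curve.occupancy_p[finite]
    p = p / p.sum()
    lam_i = curve.rate[finite]
    lam = float((p * lam_i).sum())
    if lam <= 0:
        raise ValueError("overall mean rate is zero; SI undefined")
    ratio = lam_i / lam
    terms = np.where(lam_i > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())
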