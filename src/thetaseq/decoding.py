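"""Memoryless Bayesian position decoding over 90 angular bins.

For a window of duration tau with spike-count vector n over the included
cells, the posterior under independent Poisson spiking and a flat prior is

    P(x | n)  proportional to  prod_i lambda_i(x)**n_i * exp(-tau * lambda_i(x))

computed in log space and normalized to sum to 1 over bins.  Tuning curves
are floored at a small positive rate before decoding so zero-rate bins do
not make the likelihood degenerate.

Exclusion decoders remove either all FG-cells (exFG) or a pseudo-randomly
chosen, count-matched subset of NFG-cells (exNFG); the selection is seeded
and the removed spike counts are reported so spike-count parity between the
two exclusions can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


@dataclass
class Decoder:
    rates: np.ndarray          # (n_cells, n_bins) Hz, floored
    cell_ids: np.ndarray       # (n_cells,)
    tau: float                 # window length, s
    rate_floor: float

    @property
    def n_bins(self):
        return self.rates.shape[1]


def build_decoder(tuning_rates, cell_ids, include=None, tau=0.02,
                  rate_floor=0.01) -> Decoder:
    """Assemble a decoder from per-cell tuning curves.

    ``tuning_rates`` is (n_cells, n_bins); NaN bins (never occupied) and
    rates below ``rate_floor`` are floored.  ``include`` is an optional
    boolean mask or index array selecting cells.
    """
    rates = np.asarray(tuning_rates, dtype=float)
    cell_ids = np.asarray(cell_ids)
    if include is not None:
        rates = rates[include]
        cell_ids = cell_ids[include]
    if rates.shape[0] == 0:
        raise ValueError("decoder needs at least one included cell")
    rates = np.where(np.isfinite(rates), rates, rate_floor)
    rates = np.maximum(rates, rate_floor)
    return Decoder(rates=rates, cell_ids=cell_ids, tau=float(tau),
                   rate_floor=float(rate_floor))


def decode_windows(decoder: Decoder, counts) -> np.ndarray:
    """Posterior rows for one or many windows.

    ``counts`` is (n_windows, n_cells) or (n_cells,); rows of the result
    sum to 1.
    """
    n = np.atleast_2d(np.asarray(counts, dtype=float))
    if n.shape[1] != decoder.rates.shape[0]:
        raise ValueError("count vector does not match the decoder's cells")
    if np.any(n < 0):
        raise ValueError("negative spike counts")
    log_rates = np.log(decoder.rates)                   # (cells, bins)
    log_post = n @ log_rates - decoder.tau * decoder.rates.sum(axis=0)
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    if counts is not None and np.ndim(counts) == 1:
        return post[0]
    return post


def decode_window(decoder: Decoder, counts) -> np.ndarray:
    """Single-window convenience wrapper around :func:`decode_windows`."""
    return decode_windows(decoder, np.asarray(counts, dtype=float))


def make_windows(run_intervals, width=0.02, step=0.005):
    """Sliding-window centers tiling each running interval.

    Windows of ``width`` are stepped by ``step`` through each interval,
    keeping only windows fully inside it.  Returns the concatenated center
    times (sorted within and across intervals).
    """
    centers = []
    for t0, t1 in run_intervals:
        if t1 - t0 < width:
            continue
        start = t0 + width / 2.0
        n = int(np.floor((t1 - t0 - width) / step)) + 1
        centers.append(start + step * np.arange(n))
    if not centers:
        return np.array([])
    return np.concatenate(centers)


def count_spikes(spike_times_by_cell, centers, width=0.02):
    """Spike counts per (window, cell) for the given window centers."""
    centers = np.asarray(centers, dtype=float)
    half = width / 2.0
    counts = np.zeros((centers.size, len(spike_times_by_cell)), dtype=np.int64)
    for j, st in enumerate(spike_times_by_cell):
        st = np.asarray(st, dtype=float)
        counts[:, j] = (np.searchsorted(st, centers + half, side="right")
                        - np.searchsorted(st, centers - half, side="left"))
    return counts


@dataclass
class Posterior:
    """Decoded posterior over a set of sliding windows."""

    centers: np.ndarray        # (n_windows,) s
    P: np.ndarray              # (n_windows, n_bins)
    n_spikes: np.ndarray       # (n_windows,) total spikes per window
    true_angle_deg: np.ndarray | None = None

    @property
    def map_bin(self):
        return np.argmax(self.P, axis=1)


def decode_session(decoder: Decoder, spike_times_by_cell, run_intervals,
                   width=0.02, step=0.005, true_angle_fn=None) -> Posterior:
    """Decode every sliding window tiling the running intervals."""
    centers = make_windows(run_intervals, width=width, step=step)
    if centers.size == 0:
        return Posterior(centers=centers, P=np.zeros((0, decoder.n_bins)),
                         n_spikes=np.array([], dtype=int))
    counts = count_spikes(spike_times_by_cell, centers, width=width)
    post = decode_windows(decoder, counts)
    true_angle = true_angle_fn(centers) if true_angle_fn is not None else None
    return Posterior(centers=centers, P=post, n_spikes=counts.sum(axis=1),
                     true_angle_deg=true_angle)


def make_exclusion_decoders(tuning_rates, cell_ids, fg_mask, nfg_mask,
                            seed, spike_counts=None, tau=0.02, rate_floor=0.01):
    """Raw, exFG and exNFG decoders with count-matched NFG downsampling.

    ``fg_mask`` / ``nfg_mask`` flag FG- and NFG-labeled cells among
    ``cell_ids`` (unclassified cells belong to neither and are kept in all
    decoders).  exFG removes every FG cell; exNFG removes a seeded
    pseudo-random NFG subset of the same size as the FG pool.

    Returns ``(decoders, info)`` where ``decoders`` maps
    ``{"raw", "exfg", "exnfg"}`` to Decoder objects and ``info`` records
    the removed cells and, when per-cell ``spike_counts`` are given, the
    number of spikes each exclusion removed.
    """
    fg_mask = np.asarray(fg_mask, dtype=bool)
    nfg_mask = np.asarray(nfg_mask, dtype=bool)
    n_fg = int(fg_mask.sum())
    n_nfg = int(nfg_mask.sum())
    if n_fg == 0 or n_nfg == 0:
        raise ValueError("both FG and NFG pools must be non-empty")
    if n_nfg < n_fg:
        raise ValueError("NFG pool smaller than FG pool; cannot count-match")
    rng = np.random.default_rng(seed)
    nfg_ids = np.nonzero(nfg_mask)[0]
    removed_nfg = np.sort(rng.choice(nfg_ids, size=n_fg, replace=False))
    exfg_include = ~fg_mask
    exnfg_include = np.ones_like(fg_mask)
    exnfg_include[removed_nfg] = False
    decoders = {
        "raw": build_decoder(tuning_rates, cell_ids, tau=tau, rate_floor=rate_floor),
        "exfg": build_decoder(tuning_rates, cell_ids, include=exfg_include,
                              tau=tau, rate_floor=rate_floor),
        "exnfg": build_decoder(tuning_rates, cell_ids, include=exnfg_include,
                               tau=tau, rate_floor=rate_floor),
    }
    info = {
        "removed_fg_cells": np.asarray(cell_ids)[fg_mask].tolist(),
        "removed_nfg_cells": np.asarray(cell_ids)[removed_nfg].tolist(),
        "seed": int(seed),
    }
    if spike_counts is not None:
        spike_counts = np.asarray(spike_counts)
        info["spikes_removed_exfg"] = int(spike_counts[fg_mask].sum())
        info["spikes_removed_exnfg"] = int(spike_counts[removed_nfg].sum())
    return decoders, info


def angular_error_cm(decoded_bin, true_angle_deg, n_bins=90, diameter_cm=90.0):
    """Absolute circular position error of the MAP estimate, in cm."""
    bin_deg = 360.0 / n_bins
    est_deg = (np.asarray(decoded_bin) + 0.5) * bin_deg
    diff = (est_deg - np.asarray(true_angle_deg) + 180.0) % 360.0 - 180.0
    return np.abs(np.deg2rad(diff)) * (diameter_cm / 2.0)
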