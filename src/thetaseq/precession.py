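"""Slow-gamma phase-shift (phase precession) analyses.

Within a theta cycle, slow-gamma cycles run trough to trough (phase 0
crossings of the 25-45 Hz trace).  A cell's *active* cycles are those
containing at least one of its spikes; for a run of ``k >= 2`` adjacent
active cycles the phase difference statistic is

    mean_{i=2..k}  wrap(phi_i - phi_{i-1})

where ``phi_i`` is the (circular mean) slow-gamma phase of the cell's
spikes in the i-th active cycle and wrap maps to (-180, 180].  Negative
values indicate slow-gamma phase precession.  Theta cycles qualify when
their mean z-scored slow-gamma power marks them as slow-gamma events.

The shuffle null redraws each spike's slow-gamma phase uniformly within
its own cycle (firing location preserved), recomputes the statistic, and
yields the corrected empirical p-value (r + 1) / (n + 1).

The ensemble analysis orders slow-gamma cycles around the cycle with
maximal population spiking (cycle 0) and accumulates 40 x 40 gamma-phase x
theta-phase histograms per cycle ordinal, smoothed with a circular 9-bin
boxcar along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import empirical_p, wrap_deg
from .signals import ThetaCycles


def sg_trough_times(t, sg_phase_deg):
    """Times of slow-gamma troughs (upward crossings of phase 0/360)."""
    t = np.asarray(t, dtype=float)
    ph = np.asarray(sg_phase_deg, dtype=float)
    unw = np.rad2deg(np.unwrap(np.deg2rad(ph)))
    mono = np.maximum.accumulate(unw)
    k0 = int(np.ceil(mono[0] / 360.0))
    k1 = int(np.floor(mono[-1] / 360.0))
    if k1 < k0:
        return np.array([])
    levels = 360.0 * np.arange(k0, k1 + 1)
    return np.interp(levels, mono, t)


def cell_phase_difference(phases_by_cycle):
    """Phase-difference statistic from per-active-cycle phase samples.

    ``phases_by_cycle`` is a sequence (one entry per successive adjacent
    active cycle) of spike-phase arrays in degrees; multi-spike cycles are
    reduced to their circular mean before differencing.

    Returns ``(shift_deg, k)``; raises when fewer than two cycles.
    """
    means = []
    for ph in phases_by_cycle:
        ph = np.atleast_1d(np.asarray(ph, dtype=float))
        z = np.exp(1j * np.deg2rad(ph)).mean()
        means.append(np.rad2deg(np.angle(z)) % 360.0)
    k = len(means)
    if k < 2:
        raise ValueError("need k >= 2 adjacent active cycles")
    diffs = wrap_deg(np.diff(means))
    return float(np.mean(diffs)), k


@dataclass
class ShiftData:
    """Phase-shift records plus the spike-level structure shuffles need.

    ``records`` has one row per (theta cycle, cell) with a qualifying run
    of adjacent active slow-gamma cycles.  Slots are the individual active
    cycles, ordered by record and then cycle, so adjacent slots within a
    record are adjacent slow-gamma cycles.
    """

    records: pd.DataFrame            # record_id, cycle_id, cell_id, lap, label, k, shift_deg
    spike_phase_deg: np.ndarray      # (n_spikes,)
    spike_slot: np.ndarray           # (n_spikes,) -> slot index
    slot_record: np.ndarray          # (n_slots,) -> record index

    def __len__(self):
        return len(self.records)

    def subset(self, record_mask) -> "ShiftData":
        """Restrict to the records where ``record_mask`` is True."""
        record_mask = np.asarray(record_mask, dtype=bool)
        old_ids = np.nonzero(record_mask)[0]
        remap = -np.ones(len(self.records), dtype=np.int64)
        remap[old_ids] = np.arange(old_ids.size)
        slot_keep = record_mask[self.slot_record]
        slot_remap = -np.ones(self.slot_record.size, dtype=np.int64)
        slot_remap[np.nonzero(slot_keep)[0]] = np.arange(int(slot_keep.sum()))
        spike_keep = slot_keep[self.spike_slot]
        rec = self.records.loc[record_mask].reset_index(drop=True).copy()
        rec["record_id"] = np.arange(len(rec))
        return ShiftData(records=rec,
                         spike_phase_deg=self.spike_phase_deg[spike_keep],
                         spike_slot=slot_remap[self.spike_slot[spike_keep]],
                         slot_record=remap[self.slot_record[slot_keep]])


def concat_shift_data(datas) -> ShiftData:
    """Concatenate ShiftData from several sessions (records renumbered,
    theta-cycle ids offset so they stay unique)."""
    recs, phases, spike_slots, slot_records = [], [], [], []
    rec_off = slot_off = cyc_off = 0
    for d in datas:
        r = d.records.copy()
        r["record_id"] = r["record_id"] + rec_off
        r["cycle_id"] = r["cycle_id"] + cyc_off
        recs.append(r)
        phases.append(d.spike_phase_deg)
        spike_slots.append(d.spike_slot + slot_off)
        slot_records.append(d.slot_record + rec_off)
        rec_off += len(d.records)
        slot_off += d.slot_record.size
        cyc_off += (int(d.records["cycle_id"].max()) + 1) if len(d.records) else 0
    return ShiftData(records=pd.concat(recs, ignore_index=True),
                     spike_phase_deg=np.concatenate(phases),
                     spike_slot=np.concatenate(spike_slots),
                     slot_record=np.concatenate(slot_records))


def build_shift_data(spike_table: pd.DataFrame, cycles: ThetaCycles,
                     trough_times, cell_labels=None, accepted_cells=None,
                     restrict_to_events=True, phase_col="slow_phase_deg") -> ShiftData:
    """Assemble phase-shift records from a spike-phase table.

    Spikes are assigned to theta cycles and to complete slow-gamma cycles;
    per (theta cycle, cell) the longest run of adjacent active cycles is
    kept (first run on ties) and contributes one record when its length is
    at least 2.  ``restrict_to_events`` keeps only slow-gamma-event theta
    cycles (the default, matching the single-cell analysis).
    """
    st = spike_table["t"].to_numpy(dtype=float)
    sc = spike_table["cell_id"].to_numpy()
    lap = spike_table["lap"].to_numpy() if "lap" in spike_table else np.full(st.size, -1)
    ph = spike_table[phase_col].to_numpy(dtype=float)
    if accepted_cells is not None:
        m = np.isin(sc, np.asarray(accepted_cells))
        st, sc, lap, ph = st[m], sc[m], lap[m], ph[m]

    troughs = np.asarray(trough_times, dtype=float)
    # theta cycle of each spike
    tci = np.searchsorted(cycles.t_start, st, side="right") - 1
    ok = (tci >= 0) & (st < cycles.t_end[np.clip(tci, 0, max(len(cycles) - 1, 0))])
    ok &= np.where(tci >= 0, cycles.valid[np.clip(tci, 0, None)], False)
    if restrict_to_events:
        if cycles.is_slow_gamma_event is None:
            raise ValueError("cycles lack slow-gamma event flags")
        ok &= np.where(tci >= 0, cycles.is_slow_gamma_event[np.clip(tci, 0, None)], False)
    # complete slow-gamma cycle of each spike
    gci = np.searchsorted(troughs, st, side="right") - 1
    ok &= (gci >= 0) & (gci <= troughs.size - 2)

    st, sc, lap, ph, tci, gci = (a[ok] for a in (st, sc, lap, ph, tci, gci))
    order = np.lexsort((gci, sc, tci))
    st, sc, lap, ph, tci, gci = (a[order] for a in (st, sc, lap, ph, tci, gci))

    rec_rows = []
    spike_slot = np.full(st.size, -1, dtype=np.int64)
    slot_record = []
    n_slots = 0
    i = 0
    n_sp = st.size
    while i < n_sp:
        j = i
        while j < n_sp and tci[j] == tci[i] and sc[j] == sc[i]:
            j += 1
        cyc = gci[i:j]
        uniq = np.unique(cyc)
        # longest run of consecutive cycle indices (first on ties)
        best_s, best_e = 0, 1
        s = 0
        for e in range(1, uniq.size + 1):
            if e == uniq.size or uniq[e] != uniq[e - 1] + 1:
                if e - s > best_e - best_s:
                    best_s, best_e = s, e
                s = e
        run = uniq[best_s:best_e]
        k = run.size
        if k >= 2:
            rec_id = len(rec_rows)
            phases_by_cycle = []
            for r_off, cval in enumerate(run):
                m_cyc = np.nonzero(cyc == cval)[0] + i
                spike_slot[m_cyc] = n_slots
                slot_record.append(rec_id)
                n_slots += 1
                phases_by_cycle.append(ph[m_cyc])
            shift, _ = cell_phase_difference(phases_by_cycle)
            label = None
            if cell_labels is not None:
                label = cell_labels.get(sc[i]) if isinstance(cell_labels, dict) \
                    else cell_labels.loc[sc[i]]
            rec_rows.append({"record_id": rec_id, "cycle_id": int(tci[i]),
                             "cell_id": sc[i], "lap": int(lap[i]),
                             "label": label, "k": int(k), "shift_deg": shift})
        i = j

    used = spike_slot >= 0
    records = pd.DataFrame(rec_rows, columns=["record_id", "cycle_id", "cell_id",
                                              "lap", "label", "k", "shift_deg"])
    return ShiftData(records=records,
                     spike_phase_deg=ph[used],
                     spike_slot=spike_slot[used],
                     slot_record=np.asarray(slot_record, dtype=np.int64))


def _record_shifts(data: ShiftData, phases_deg):
    """Per-record mean adjacent phase difference for given spike phases."""
    n_slots = data.slot_record.size
    rad = np.deg2rad(phases_deg)
    zc = np.bincount(data.spike_slot, weights=np.cos(rad), minlength=n_slots)
    zs = np.bincount(data.spike_slot, weights=np.sin(rad), minlength=n_slots)
    slot_phase = np.rad2deg(np.arctan2(zs, zc)) % 360.0
    same = data.slot_record[1:] == data.slot_record[:-1]
    diffs = wrap_deg(slot_phase[1:] - slot_phase[:-1])[same]
    rec_of_diff = data.slot_record[1:][same]
    n_rec = len(data.records)
    sums = np.bincount(rec_of_diff, weights=diffs, minlength=n_rec)
    cnts = np.bincount(rec_of_diff, minlength=n_rec)
    return sums / np.maximum(cnts, 1)


def aggregate_phase_shift(records: pd.DataFrame, level="sequence",
                          by=None) -> pd.DataFrame:
    """Aggregate record shifts per theta cycle or per cell.

    ``level='sequence'`` averages across cells within each theta cycle;
    ``level='cell'`` averages each cell across theta cycles.  ``by`` adds
    stratification columns (e.g. ``["lap", "label"]``).  Shifts are
    arithmetic means of already-wrapped values.
    """
    key = {"sequence": "cycle_id", "cell": "cell_id"}.get(level)
    if key is None:
        raise ValueError("level must be 'sequence' or 'cell'")
    cols = [key] + (list(by) if by else [])
    out = (records.groupby(cols, dropna=False)["shift_deg"]
           .agg(shift_deg="mean", n="size").reset_index())
    return out


def shuffle_null(data: ShiftData, n_shuffles=1000, seed=0, level="sequence",
                 stat="median"):
    """Shuffle null for the aggregated phase-shift statistic.

    Each shuffle assigns every spike a uniform random slow-gamma phase
    within its own cycle (spike counts per cycle and cell are preserved
    exactly), recomputes record shifts, aggregates at ``level`` and takes
    the ``stat`` (median or mean).  Returns observed statistic, the null
    sample, the 95% CI of the null, and one-sided empirical p-values.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    if level == "sequence":
        group = data.records["cycle_id"].to_numpy()
    elif level == "cell":
        group = data.records["cell_id"].to_numpy()
    elif level == "record":
        group = data.records["record_id"].to_numpy()
    else:
        raise ValueError("level must be 'sequence', 'cell' or 'record'")
    _, gidx = np.unique(group, return_inverse=True)
    n_groups = gidx.max() + 1 if gidx.size else 0
    stat_fn = {"median": np.median, "mean": np.mean}[stat]

    def aggregate(shifts):
        sums = np.bincount(gidx, weights=shifts, minlength=n_groups)
        cnts = np.bincount(gidx, minlength=n_groups)
        return stat_fn(sums / cnts)

    observed = aggregate(_record_shifts(data, data.spike_phase_deg))
    null = np.empty(n_shuffles)
    n_spk = data.spike_phase_deg.size
    for s in range(n_shuffles):
        phases = rng.uniform(0.0, 360.0, size=n_spk)
        null[s] = aggregate(_record_shifts(data, phases))
    ci = (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5)))
    return {
        "observed": float(observed),
        "null": null,
        "ci95": ci,
        "p_left": empirical_p(observed, null, side="left"),
        "p_right": empirical_p(observed, null, side="right"),
        "n_records": len(data.records),
    }


def quadrant_analysis(data: ShiftData, sequences: pd.DataFrame,
                      corr_col="corr_raw", n_shuffles=1000, seed=0):
    """Joint distribution of per-sequence phase shift and corr_w.

    Quadrant 1 is (shift < 0, corr_w > 0): the signature of slow-gamma
    phase precession inside a forward sweep.  The observed Q1 probability
    is compared against shuffles that redraw spike phases uniformly within
    their cycles (corr_w values stay fixed); the one-sided corrected
    empirical p is small when Q1 holds more mass than chance.  Sequences
    with shift or corr exactly 0 belong to no quadrant and are excluded
    from the normalization (their count is reported).
    """
    per_seq = aggregate_phase_shift(data.records, level="sequence")
    merged = sequences.merge(per_seq, on="cycle_id", how="inner")
    corr = merged[corr_col].to_numpy(dtype=float)
    shift = merged["shift_deg"].to_numpy(dtype=float)
    defined = np.isfinite(corr) & np.isfinite(shift)
    corr, shift = corr[defined], shift[defined]
    cyc = merged["cycle_id"].to_numpy()[defined]

    def quadrants(sh, co):
        on_axis = (sh == 0) | (co == 0)
        sh, co = sh[~on_axis], co[~on_axis]
        n = sh.size
        if n == 0:
            return np.full(4, np.nan), int(on_axis.sum())
        q = np.array([
            np.sum((sh < 0) & (co > 0)),  # Q1
            np.sum((sh > 0) & (co > 0)),  # Q2
            np.sum((sh < 0) & (co < 0)),  # Q3
            np.sum((sh > 0) & (co < 0)),  # Q4
        ]) / n
        return q, int(on_axis.sum())

    q_obs, n_excl = quadrants(shift, corr)
    # map records -> position among the analyzed sequences, for the shuffles
    cyc_to_row = {c: i for i, c in enumerate(cyc)}
    rec_cyc = data.records["cycle_id"].to_numpy()
    rec_row = np.array([cyc_to_row.get(c, -1) for c in rec_cyc])
    in_use = rec_row >= 0
    rng = np.random.default_rng(seed)
    null_q1 = np.empty(n_shuffles)
    n_rows = cyc.size
    for s in range(n_shuffles):
        phases = rng.uniform(0.0, 360.0, size=data.spike_phase_deg.size)
        rec_shift = _record_shifts(data, phases)
        sums = np.bincount(rec_row[in_use], weights=rec_shift[in_use], minlength=n_rows)
        cnts = np.bincount(rec_row[in_use], minlength=n_rows)
        sh = sums / np.maximum(cnts, 1)
        q, _ = quadrants(sh, corr)
        null_q1[s] = q[0]
    # one-sided: small p means observed Q1 above the shuffle distribution
    p = empirical_p(q_obs[0], null_q1, side="right")
    return {
        "n_sequences": int(n_rows),
        "n_on_axis_excluded": n_excl,
        "quadrants": {"Q1": q_obs[0], "Q2": q_obs[1], "Q3": q_obs[2], "Q4": q_obs[3]},
        "q1_null": null_q1,
        "p_q1": float(p),
        "seed": int(seed),
        "n_shuffles": int(n_shuffles),
    }


def order_gamma_cycles(cycles: ThetaCycles, trough_times, spike_table: pd.DataFrame,
                       accepted_cells=None, max_ordinal=1) -> pd.DataFrame:
    """Order complete slow-gamma cycles around the maximal-spiking cycle.

    For each valid theta cycle, slow-gamma cycles fully contained in it are
    enumerated; the one with the most spikes across all (accepted) cells is
    cycle 0 (earliest on ties), earlier cycles get negative ordinals, later
    ones positive, and the analysis is limited to ordinals within
    ``[-max_ordinal, max_ordinal]``.
    """
    troughs = np.asarray(trough_times, dtype=float)
    st = spike_table["t"].to_numpy(dtype=float)
    sc = spike_table["cell_id"].to_numpy()
    if accepted_cells is not None:
        m = np.isin(sc, np.asarray(accepted_cells))
        st = st[m]
    gci = np.searchsorted(troughs, st, side="right") - 1
    counts = np.bincount(gci[(gci >= 0) & (gci < troughs.size - 1)],
                         minlength=max(troughs.size - 1, 0))
    rows = []
    for ti in range(len(cycles)):
        if not cycles.valid[ti]:
            continue
        t0, t1 = cycles.t_start[ti], cycles.t_end[ti]
        first = int(np.searchsorted(troughs, t0, side="left"))
        # complete cycles: [troughs[i], troughs[i+1]] inside [t0, t1]
        cands = []
        i = first
        while i + 1 < troughs.size and troughs[i + 1] <= t1 + 1e-12:
            if troughs[i] >= t0 - 1e-12:
                cands.append(i)
            i += 1
        if not cands:
            continue
        c_counts = counts[cands] if counts.size else np.zeros(len(cands), dtype=int)
        zero = cands[int(np.argmax(c_counts))]   # argmax takes the earliest tie
        for c in cands:
            ordinal = c - zero
            if abs(ordinal) <= max_ordinal:
                rows.append({"theta_cycle": ti, "sg_cycle": int(c),
                             "ordinal": int(ordinal),
                             "n_spikes": int(counts[c]) if counts.size else 0})
    return pd.DataFrame(rows, columns=["theta_cycle", "sg_cycle", "ordinal", "n_spikes"])


def _circular_boxcar(h, width, axis):
    k = np.zeros(h.shape[axis])
    half = width // 2
    k[:half + 1] = 1.0
    if half > 0:
        k[-half:] = 1.0
    k /= k.sum()
    hf = np.fft.fft(h, axis=axis)
    kf = np.fft.fft(k)
    shape = [1, 1]
    shape[axis] = k.size
    return np.real(np.fft.ifft(hf * kf.reshape(shape), axis=axis))


def ensemble_phase_histograms(spike_table: pd.DataFrame, ordered: pd.DataFrame,
                              cycles: ThetaCycles, trough_times,
                              n_bins=40, smooth_bins=9, min_active_cycles=2,
                              accepted_cells=None):
    """2-D (slow-gamma phase x theta phase) histograms per cycle ordinal.

    A cell's spikes enter a theta cycle's histograms only when they span at
    least ``min_active_cycles`` slow-gamma cycles within it.  Histograms
    are ``n_bins`` x ``n_bins`` and smoothed with a circular
    ``smooth_bins``-wide boxcar along each axis (mass conserved).
    """
    troughs = np.asarray(trough_times, dtype=float)
    st = spike_table["t"].to_numpy(dtype=float)
    sc = spike_table["cell_id"].to_numpy()
    sg_ph = spike_table["slow_phase_deg"].to_numpy(dtype=float)
    th_ph = spike_table["theta_phase_deg"].to_numpy(dtype=float)
    if accepted_cells is not None:
        m = np.isin(sc, np.asarray(accepted_cells))
        st, sc, sg_ph, th_ph = st[m], sc[m], sg_ph[m], th_ph[m]
    tci = np.searchsorted(cycles.t_start, st, side="right") - 1
    ok = (tci >= 0) & (st < cycles.t_end[np.clip(tci, 0, max(len(cycles) - 1, 0))])
    gci = np.searchsorted(troughs, st, side="right") - 1
    ok &= (gci >= 0) & (gci <= troughs.size - 2)
    st, sc, sg_ph, th_ph, tci, gci = (a[ok] for a in (st, sc, sg_ph, th_ph, tci, gci))

    ord_map = {(r.theta_cycle, r.sg_cycle): r.ordinal for r in ordered.itertuples()}
    # cell span filter per theta cycle
    span = pd.DataFrame({"tc": tci, "cell": sc, "gc": gci}).groupby(
        ["tc", "cell"])["gc"].nunique()
    good_pairs = set(span[span >= min_active_cycles].index)

    hists = {o: np.zeros((n_bins, n_bins)) for o in range(-1, 2)}
    width = 360.0 / n_bins
    for i in range(st.size):
        key = (int(tci[i]), int(gci[i]))
        if key not in ord_map:
            continue
        if (int(tci[i]), sc[i]) not in good_pairs:
            continue
        o = ord_map[key]
        gi = min(int(sg_ph[i] // width), n_bins - 1)
        tj = min(int(th_ph[i] // width), n_bins - 1)
        hists[o][gi, tj] += 1
    out = {}
    for o, h in hists.items():
        sm = _circular_boxcar(_circular_boxcar(h, smooth_bins, 0), smooth_bins, 1)
        out[o] = sm
    return out
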