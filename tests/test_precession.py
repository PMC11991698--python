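"""Slow-gamma phase-shift statistics, shuffle nulls, quadrant analysis."""

import numpy as np
import pandas as pd
import pytest

from thetaseq.circstats import wrap_deg
from thetaseq.precession import (ShiftData, _record_shifts, aggregate_phase_shift,
                                 cell_phase_difference, concat_shift_data,
                                 ensemble_phase_histograms, order_gamma_cycles,
                                 quadrant_analysis, sg_trough_times,
                                 shuffle_null)
from thetaseq.signals import ThetaCycles


class TestCellPhaseDifference:
    @pytest.mark.parametrize("phases, expected", [
        ([[350.0], [290.0], [230.0]], -60.0),
        ([[10.0], [350.0]], -20.0),          # wrapped difference
        ([[123.0], [123.0], [123.0]], 0.0),
    ])
    def test_examples(self, phases, expected):
        shift, k = cell_phase_difference(phases)
        assert shift == pytest.approx(expected, abs=1e-9)
        assert k == len(phases)

    def test_multi_spike_cycles_use_circular_mean(self):
        shift, _ = cell_phase_difference([[350.0, 10.0], [300.0]])
        assert shift == pytest.approx(-60.0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        phases = [rng.uniform(0, 360, 3) for _ in range(4)]
        s1, _ = cell_phase_difference(phases)
        s2, _ = cell_phase_difference([(p + 111.0) % 360.0 for p in phases])
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_single_cycle_rejected(self):
        with pytest.raises(ValueError):
            cell_phase_difference([[10.0]])


class TestOrdering:
    def _cycles(self):
        return ThetaCycles(t_start=np.array([0.0]), t_end=np.array([0.125]),
                           valid=np.array([True]))

    def test_argmax_cycle_is_zero(self):
        troughs = np.array([0.0, 0.03, 0.06, 0.09, 0.12])
        spikes = pd.DataFrame({
            "cell_id": [0] * 10,
            "t": [0.01, 0.02, 0.031, 0.035, 0.04, 0.045, 0.05, 0.061, 0.07, 0.08],
        })  # counts per cycle: 2, 5, 3
        ordered = order_gamma_cycles(self._cycles(), troughs, spikes)
        by_cycle = ordered.set_index("sg_cycle")["ordinal"]
        assert by_cycle[0] == -1 and by_cycle[1] == 0 and by_cycle[2] == 1

    def test_tie_breaks_to_earlier_cycle(self):
        troughs = np.array([0.0, 0.03, 0.06, 0.09])
        spikes = pd.DataFrame({"cell_id": [0] * 8,
                               "t": [0.01, 0.012, 0.02, 0.025,
                                     0.031, 0.04, 0.045, 0.05]})  # 4 vs 4
        ordered = order_gamma_cycles(self._cycles(), troughs, spikes)
        assert ordered.set_index("sg_cycle")["ordinal"][0] == 0

    def test_ordinals_limited_to_pm_one(self, small_result, small_session):
        res = small_result
        troughs = sg_trough_times(small_session.lfp.t, res.phases["slow"])
        ordered = order_gamma_cycles(res.cycles, troughs, res.spike_table)
        assert set(ordered["ordinal"]).issubset({-1, 0, 1})


class TestShiftData:
    def test_records_from_pipeline_are_wrapped_and_k_at_least_2(self, small_result):
        data = small_result.shift_data
        assert len(data) > 0
        assert (data.records["k"] >= 2).all()
        assert (data.records["shift_deg"] > -180.0).all()
        assert (data.records["shift_deg"] <= 180.0).all()

    def test_vectorized_shifts_match_scalar_statistic(self, small_result):
        data = small_result.shift_data
        shifts = _record_shifts(data, data.spike_phase_deg)
        assert np.allclose(shifts, data.records["shift_deg"], atol=1e-9)

    def test_subset_keeps_consistency(self, small_result):
        data = small_result.shift_data
        mask = data.records["label"].to_numpy() == "NFG"
        if mask.sum() == 0:
            pytest.skip("no NFG records in this session")
        sub = data.subset(mask)
        shifts = _record_shifts(sub, sub.spike_phase_deg)
        assert np.allclose(shifts, sub.records["shift_deg"], atol=1e-9)

    def test_concat_preserves_record_shifts(self, small_result):
        data = small_result.shift_data
        both = concat_shift_data([data, data])
        shifts = _record_shifts(both, both.spike_phase_deg)
        assert np.allclose(shifts, both.records["shift_deg"], atol=1e-9)
        assert len(both) == 2 * len(data)


class TestAggregation:
    def test_single_record_identity(self):
        rec = pd.DataFrame({"record_id": [0], "cycle_id": [3], "cell_id": [7],
                            "lap": [0], "label": ["FG"], "k": [2],
                            "shift_deg": [-42.0]})
        agg = aggregate_phase_shift(rec, level="sequence")
        assert agg["shift_deg"].iloc[0] == pytest.approx(-42.0)

    def test_opposite_shifts_cancel_within_sequence(self):
        rec = pd.DataFrame({"record_id": [0, 1], "cycle_id": [3, 3],
                            "cell_id": [1, 2], "lap": [0, 0],
                            "label": ["FG", "NFG"], "k": [2, 2],
                            "shift_deg": [-60.0, 60.0]})
        agg = aggregate_phase_shift(rec, level="sequence")
        assert agg["shift_deg"].iloc[0] == pytest.approx(0.0)

    def test_cell_level_stratified_by_lap(self):
        rec = pd.DataFrame({"record_id": range(4), "cycle_id": [0, 1, 2, 3],
                            "cell_id": [5, 5, 5, 5], "lap": [0, 0, 1, 1],
                            "label": ["FG"] * 4, "k": [2] * 4,
                            "shift_deg": [-50.0, -70.0, 10.0, 30.0]})
        agg = aggregate_phase_shift(rec, level="cell", by=["lap"])
        assert agg.loc[agg.lap == 0, "shift_deg"].iloc[0] == pytest.approx(-60.0)
        assert agg.loc[agg.lap == 1, "shift_deg"].iloc[0] == pytest.approx(20.0)


class TestShuffleNull:
    def test_spike_counts_preserved_and_null_centered(self, small_result):
        data = small_result.shift_data
        res = shuffle_null(data, n_shuffles=200, seed=4, level="sequence")
        lo, hi = res["ci95"]
        assert lo < 0 < hi  # uniform-phase null median straddles zero
        assert res["null"].size == 200

    def test_injected_precession_beats_null(self, small_result):
        data = small_result.shift_data
        res = shuffle_null(data, n_shuffles=200, seed=4, level="sequence")
        assert res["observed"] < -30.0
        assert res["p_left"] < 0.05

    def test_extreme_observation_floor_p(self, small_result):
        data = small_result.shift_data
        res = shuffle_null(data, n_shuffles=200, seed=4)
        assert res["p_left"] >= 1.0 / 201.0


class TestQuadrants:
    def _mock(self, rng, n_seq=80, precess=True, corr_positive=True):
        """Sequence records built directly: one cell, two active cycles."""
        records = []
        phases = []
        spike_slot = []
        slot_record = []
        for i in range(n_seq):
            base = rng.uniform(0, 360)
            step = -60.0 if precess else rng.uniform(-180, 180)
            ph = [base % 360.0, (base + step) % 360.0]
            shift = wrap_deg(ph[1] - ph[0])
            records.append({"record_id": i, "cycle_id": i, "cell_id": 0,
                            "lap": 0, "label": "FG", "k": 2,
                            "shift_deg": float(shift)})
            phases.extend(ph)
            spike_slot.extend([2 * i, 2 * i + 1])
            slot_record.extend([i, i])
        data = ShiftData(records=pd.DataFrame(records),
                         spike_phase_deg=np.array(phases),
                         spike_slot=np.array(spike_slot),
                         slot_record=np.array(slot_record))
        if corr_positive:
            corr = rng.uniform(0.1, 0.8, n_seq)
        else:
            corr = rng.uniform(-0.5, 0.5, n_seq)
        seqs = pd.DataFrame({"cycle_id": np.arange(n_seq), "corr_raw": corr})
        return data, seqs

    def test_joint_injection_significant(self, rng):
        data, seqs = self._mock(rng, precess=True, corr_positive=True)
        out = quadrant_analysis(data, seqs, n_shuffles=200, seed=9)
        assert out["quadrants"]["Q1"] > 0.8
        assert out["p_q1"] < 0.05

    def test_no_injection_not_systematically_significant(self, rng):
        ps = []
        for i in range(30):
            data, seqs = self._mock(rng, n_seq=50, precess=False,
                                    corr_positive=False)
            ps.append(quadrant_analysis(data, seqs, n_shuffles=100,
                                        seed=i)["p_q1"])
        assert np.mean(np.asarray(ps) < 0.05) < 0.2

    def test_quadrant_probabilities_sum_to_one(self, rng):
        data, seqs = self._mock(rng)
        out = quadrant_analysis(data, seqs, n_shuffles=50, seed=2)
        assert sum(out["quadrants"].values()) == pytest.approx(1.0, abs=1e-9)


class TestEnsembleHistograms:
    def test_mass_conserved_by_circular_smoothing(self, small_result,
                                                  small_session):
        res = small_result
        troughs = sg_trough_times(small_session.lfp.t, res.phases["slow"])
        ordered = order_gamma_cycles(res.cycles, troughs, res.spike_table)
        hists = ensemble_phase_histograms(res.spike_table, ordered, res.cycles,
                                          troughs)
        assert set(hists) == {-1, 0, 1}
        for h in hists.values():
            assert h.shape == (40, 40)
            assert h.sum() >= 0
        # smoothing conserves total mass: re-run with no smoothing
        raw = ensemble_phase_histograms(res.spike_table, ordered, res.cycles,
                                        troughs, smooth_bins=1)
        for o in (-1, 0, 1):
            assert hists[o].sum() == pytest.approx(raw[o].sum(), abs=1e-9)

    def test_injected_precession_orders_ordinal_phases(self):
        from thetaseq import SimConfig, analyze_session, simulate_session
        cfg = SimConfig(n_cells=30, n_laps=3, sg_precession_slope=-60.0)
        s = simulate_session(cfg, seed=8)
        res = analyze_session(s, seed=8, do_decoding=False, do_precession=True,
                              n_shuffles=0)
        troughs = sg_trough_times(s.lfp.t, res.phases["slow"])
        ordered = order_gamma_cycles(res.cycles, troughs, res.spike_table)
        # paired comparison: theta cycles with spikes in both ordinals -1
        # and +1; their circular-mean phases differ by ~ two slopes
        tab = res.spike_table
        st = tab["t"].to_numpy()
        ph = tab["slow_phase_deg"].to_numpy()
        gci = np.searchsorted(troughs, st, "right") - 1
        tci = np.searchsorted(res.cycles.t_start, st, "right") - 1
        omap = {(r.theta_cycle, r.sg_cycle): r.ordinal
                for r in ordered.itertuples()}
        rows = [(int(tci[i]), omap[(int(tci[i]), int(gci[i]))], ph[i])
                for i in range(st.size)
                if (int(tci[i]), int(gci[i])) in omap]
        df = pd.DataFrame(rows, columns=["tc", "o", "ph"])
        cm = df.groupby(["tc", "o"])["ph"].apply(
            lambda p: np.angle(np.exp(1j * np.deg2rad(p)).mean(),
                               deg=True) % 360).unstack()
        both = cm.dropna(subset=[-1, 1])
        assert len(both) > 30
        d = wrap_deg(both[-1] - both[1])
        mean_d = np.rad2deg(np.angle(np.exp(1j * np.deg2rad(d)).mean()))
        assert mean_d == pytest.approx(120.0, abs=30.0)
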