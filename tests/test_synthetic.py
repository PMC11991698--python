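"""Ground-truth generator: reproducibility, geometry, injected structure."""

import numpy as np
import pandas as pd
import pytest

from thetaseq import SimConfig, simulate_session
from thetaseq.circstats import wrap_deg
from thetaseq.placecells import estimate_speed
from thetaseq.signals import (bandpass, detect_gamma_episodes, instantaneous_phase,
                              morlet_band_power, zscore_in_intervals)
from thetaseq.synthetic import generate_position, generate_spikes, synthesize_lfp


class TestPosition:
    def test_constant_speed_recovered_by_estimator(self):
        cfg = SimConfig(run_speed_sd=0.0, run_speed_mean=30.0, n_laps=2, n_cells=1)
        pos = generate_position(cfg, seed=0)
        v = estimate_speed(pos.t, pos.x, pos.y)
        for a, b in pos.laps:
            m = (pos.t > a + 0.2) & (pos.t < b - 0.2)
            assert np.allclose(v[m], 30.0, atol=1.0)

    def test_lap_count_and_monotonic_angle(self):
        cfg = SimConfig(n_laps=5, n_cells=1)
        pos = generate_position(cfg, seed=3)
        assert len(pos.laps) == 5
        for a, b in pos.laps:
            m = (pos.t >= a) & (pos.t < b)
            assert np.all(np.diff(pos.angle_unwrapped_deg[m]) >= 0)

    def test_lap_path_length_matches_circumference(self):
        cfg = SimConfig(n_laps=1, n_cells=1)
        pos = generate_position(cfg, seed=4)
        a, b = pos.laps[0]
        m = (pos.t >= a) & (pos.t <= b)
        steps = np.hypot(np.diff(pos.x[m]), np.diff(pos.y[m])).sum()
        # oracle: circumference of the generated radius (= 45 cm -> ~283 cm)
        assert steps == pytest.approx(np.pi * cfg.track_inner_diameter, rel=0.02)

    def test_rest_gaps_have_zero_speed(self):
        cfg = SimConfig(n_laps=2, n_cells=1)
        pos = generate_position(cfg, seed=5)
        gap = (pos.t > pos.laps[0][1] + 0.2) & (pos.t < pos.laps[1][0] - 0.2)
        assert np.allclose(pos.speed_true[gap], 0.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_laps=0)
        with pytest.raises(ValueError):
            SimConfig(pos_fs=-25.0)


class TestReproducibility:
    def test_bit_identical_given_config_and_seed(self):
        cfg = SimConfig(n_cells=5, n_laps=2)
        s1 = simulate_session(cfg, seed=42)
        s2 = simulate_session(cfg, seed=42)
        assert np.array_equal(s1.lfp.lfp, s2.lfp.lfp)
        pd.testing.assert_frame_equal(s1.spikes, s2.spikes)
        assert np.array_equal(s1.position.x, s2.position.x)

    def test_seeds_differ(self):
        cfg = SimConfig(n_cells=5, n_laps=2)
        s1 = simulate_session(cfg, seed=1)
        s2 = simulate_session(cfg, seed=2)
        assert not np.array_equal(s1.lfp.lfp, s2.lfp.lfp)


class TestLfp:
    def test_recomputed_theta_phase_matches_ground_truth(self, small_session):
        lfp = small_session.lfp
        ph = instantaneous_phase(bandpass(lfp.lfp, lfp.fs, (4.0, 12.0)))
        m = np.zeros(lfp.t.size, bool)
        for a, b in small_session.laps:
            m |= (lfp.t >= a) & (lfp.t < b)
        err = wrap_deg(ph[m] - lfp.theta_phase_deg[m])
        assert np.sqrt(np.mean(err**2)) < 15.0

    def test_no_bursts_means_no_episodes(self):
        cfg = SimConfig(n_cells=1, n_laps=2, sg_burst_prob=0.0, fg_burst_prob=0.0)
        s = simulate_session(cfg, seed=9)
        zs = zscore_in_intervals(s.lfp.t, morlet_band_power(
            s.lfp.lfp, s.lfp.fs, (25.0, 45.0)), s.laps)
        zf = zscore_in_intervals(s.lfp.t, morlet_band_power(
            s.lfp.lfp, s.lfp.fs, (65.0, 100.0)), s.laps)
        # without bursts, z >= 3 only in the chance-level upper tail
        in_lap = np.zeros(s.lfp.t.size, bool)
        for a, b in s.laps:
            in_lap |= (s.lfp.t >= a) & (s.lfp.t < b)
        # band power is right-skewed, so the chance tail is permitted a
        # couple of percent
        assert np.mean(zs[in_lap] >= 3.0) < 0.025
        assert np.mean(zf[in_lap] >= 3.0) < 0.025
        eps = detect_gamma_episodes(s.lfp.t, zs, zf)
        lap_seconds = sum(b - a for a, b in s.laps)
        # chance-level crossings only: on the order of one per second at most
        assert len(eps) < 1.5 * lap_seconds

    def test_injected_strong_bursts_recovered(self):
        # sparse strong slow bursts, no fast bursts: the episode detector
        # should recover nearly all of them with accurate centers
        cfg = SimConfig(n_cells=1, n_laps=4, sg_burst_prob=0.05,
                        sg_burst_amp_scale=(6.0, 9.0), sg_burst_duty=1.0,
                        sg_freq_jitter_hz=2.0, fg_burst_prob=0.0)
        s = simulate_session(cfg, seed=21)
        zs = zscore_in_intervals(s.lfp.t, morlet_band_power(
            s.lfp.lfp, s.lfp.fs, (25.0, 45.0)), s.laps)
        # no fast-gamma stream: isolates slow-burst recovery from the
        # cross-rhythm veto (chance fast-band tails are tested elsewhere)
        eps = detect_gamma_episodes(s.lfp.t, zs, np.zeros_like(zs))
        centers = np.array([e.t_center for e in eps if e.rhythm == "slow"])
        bursts = s.lfp.bursts.query("rhythm == 'slow'")
        assert len(bursts) >= 5
        hits = sum(np.any(np.abs(centers - c) <= 0.010) for c in bursts.t_center)
        assert hits >= 0.9 * len(bursts)


class TestSpikes:
    def test_zero_peak_rate_zero_spikes(self):
        cfg = SimConfig(n_cells=3, n_laps=1, peak_rate=0.0, noise_rate=0.0)
        s = simulate_session(cfg, seed=2)
        assert len(s.spikes) == 0

    def test_spike_count_matches_rate_integral(self):
        # single cell, no gamma gains: expected count = integral of the rate
        cfg = SimConfig(n_cells=1, n_laps=3, fg_fraction=0.0,
                        sg_precession_slope=0.0, noise_rate=0.0,
                        run_speed_sd=0.0, sweep_half_span_cm=0.0)
        pos = generate_position(cfg, seed=6)
        lfp = synthesize_lfp(pos, cfg, seed=6)
        spikes, cells = generate_spikes(pos, lfp, cfg, seed=6)
        from thetaseq.synthetic import _field_kappa
        ang = np.interp(lfp.t, pos.t, pos.angle_unwrapped_deg)
        kappa = _field_kappa(cfg.field_width)
        rate = cfg.peak_rate * np.exp(
            kappa * (np.cos(np.deg2rad(ang - cells.center_deg[0])) - 1.0))
        expected = rate.sum() / lfp.fs
        assert abs(len(spikes) - expected) <= 3.0 * np.sqrt(expected)

    def test_fg_cells_lock_to_ground_truth_fast_phase(self, small_session):
        s = small_session
        fs = s.lfp.fs
        devs = []
        for cid in np.nonzero(s.cells.is_fg.to_numpy())[0]:
            st = s.spikes.loc[s.spikes.cell_id == cid, "t"].to_numpy()
            idx = np.clip(np.round(st * fs).astype(int), 0, s.lfp.t.size - 1)
            ph = s.lfp.fg_phase_deg[idx]
            mean = np.angle(np.exp(1j * np.deg2rad(ph)).mean(), deg=True) % 360
            devs.append(abs(wrap_deg(mean - 180.0)))
        # circular-mean SE at kappa=0.8 and ~70 spikes is ~18 deg per cell
        assert np.median(devs) < 25.0
        assert max(devs) < 60.0

    def test_sg_precession_slope_recovered_from_truth(self):
        # adjacent-cycle phase differences of ground-truth phases track the
        # injected slope
        cfg = SimConfig(n_cells=10, n_laps=2, sg_precession_slope=-60.0)
        s = simulate_session(cfg, seed=13)
        fs = s.lfp.fs
        sg_cyc = np.floor(s.lfp.sg_phase_unwrapped_deg / 360.0).astype(int)
        th_cyc = np.floor(cfg.theta_freq * s.lfp.t).astype(int)
        in_lap = np.zeros(0, bool)
        diffs = []
        for cid in range(10):
            st = s.spikes.loc[s.spikes.cell_id == cid, "t"].to_numpy()
            keep = np.zeros(st.size, bool)
            for a, b in s.laps:  # precession is injected on the track only
                keep |= (st >= a) & (st < b)
            st = st[keep]
            idx = np.clip(np.round(st * fs).astype(int), 0, s.lfp.t.size - 1)
            df = pd.DataFrame({"th": th_cyc[idx], "sg": sg_cyc[idx],
                               "ph": s.lfp.sg_phase_deg[idx]})
            for th, grp in df.groupby("th"):
                cyc_means = grp.groupby("sg")["ph"].apply(
                    lambda p: np.angle(np.exp(1j * np.deg2rad(p)).mean(),
                                       deg=True) % 360)
                cycles = cyc_means.index.to_numpy()
                for i in range(1, len(cycles)):
                    if cycles[i] == cycles[i - 1] + 1:
                        diffs.append(wrap_deg(cyc_means.iloc[i]
                                              - cyc_means.iloc[i - 1]))
        assert len(diffs) > 100
        assert np.mean(diffs) == pytest.approx(-60.0, abs=8.0)
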