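"""Synthetic-cohort generator: determinism, calibration, ground truth."""
import numpy as np
import pytest

from thermoknee import (ConfigurationError, SyntheticConfig, ZONES, KneeZone,
                        generate_kinematics, generate_participant,
                        render_thermal, simulate_loadcells, simulate_tracker,
                        total_weight, zone_slopes_c_per_min)

from conftest import make_cfg, make_noiseless_cfg


class TestKinematics:
    def test_cycle_count_in_cadence_range(self):
        # 600 s of cycles drawn uniformly in [3, 4] s -> 150..200 cycles
        cfg = SyntheticConfig(duration_s=600.0, seed=2)
        gt = generate_kinematics(cfg)
        assert 150 <= gt.cycle_count <= 200

    def test_cycle_count_matches_crossing_oracle(self):
        # independent oracle: upward crossings of half amplitude
        cfg = make_cfg(seed=7, duration_s=120.0)
        gt = generate_kinematics(cfg)
        half = 0.5 * cfg.excursion_amplitude_px
        up = np.sum((gt.excursion_px[:-1] < half) & (gt.excursion_px[1:] >= half))
        assert gt.cycle_count == up

    def test_zero_amplitude_is_static_standing(self):
        cfg = make_cfg(excursion_amplitude_px=0.0)
        gt = generate_kinematics(cfg)
        assert np.all(gt.phase == "standing")
        assert np.all(gt.zone_centers_px == gt.zone_centers_px[0])

    def test_baseline_temps_at_t0(self):
        cfg = make_cfg()
        gt = generate_kinematics(cfg)
        for zi, z in enumerate(ZONES):
            assert gt.zone_temps_c[0, zi] == pytest.approx(
                cfg.zone_baselines_c[z.region], abs=1e-12)

    def test_trend_slope_reaches_configured_excursion(self):
        # SM slope +0.08 degC/min over 10 min -> +0.8 degC end-to-start
        cfg = SyntheticConfig(duration_s=600.0)
        gt = generate_kinematics(cfg)
        zi = ZONES.index(KneeZone.RSM)
        delta = gt.zone_temps_c[-1, zi] - gt.zone_temps_c[0, zi]
        expected = 0.08 * (gt.times[-1] / 60.0)
        assert delta == pytest.approx(expected, rel=1e-9)

    def test_centers_within_bounds_and_error_when_too_small(self):
        gt = generate_kinematics(make_cfg())
        assert gt.zone_centers_px[:, :, 0].min() >= 0
        assert gt.zone_centers_px[:, :, 0].max() < 128
        with pytest.raises(ConfigurationError):
            generate_kinematics(make_cfg(width_px=40, height_px=30))

    def test_phase_labels_follow_excursion_thresholds(self):
        cfg = make_cfg()
        gt = generate_kinematics(cfg)
        amp = cfg.excursion_amplitude_px
        assert np.all(gt.excursion_px[gt.phase == "sitting"] < 0.25 * amp)
        assert np.all(gt.excursion_px[gt.phase == "standing"] > 0.75 * amp)

    def test_coupling_gain_adds_slope_to_heavier_leg_sm(self):
        cfg = make_cfg(left_share=0.53, coupling_gain=1.0)
        slopes = zone_slopes_c_per_min(cfg)
        lsm = slopes[ZONES.index(KneeZone.LSM)]
        rsm = slopes[ZONES.index(KneeZone.RSM)]
        assert lsm - rsm == pytest.approx(1.0 * 0.03, abs=1e-12)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"left_share": 0.0}, {"left_share": 1.0}, {"rear_share": -0.1},
        {"frame_rate_hz": 0.0}, {"thermal_noise_c": -1.0},
        {"tracker_rms_px": -1.0}, {"cycle_period_s": (4.0, 3.0)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            make_cfg(**kwargs)


class TestThermalRendering:
    def test_noiseless_static_field_is_constant(self):
        cfg = make_noiseless_cfg(
            excursion_amplitude_px=0.0,
            zone_trends_c_per_min={}, coupling_gain=0.0, duration_s=2.0)
        gt = generate_kinematics(cfg)
        seq = render_thermal(cfg, gt)
        assert np.array_equal(seq.frames[0], seq.frames[-1])

    def test_zone_centre_pixels_carry_true_temperature(self):
        cfg = make_noiseless_cfg(duration_s=10.0)
        gt = generate_kinematics(cfg)
        seq = render_thermal(cfg, gt, indices=[0, 100, 199])
        for k, i in enumerate((0, 100, 199)):
            for zi in range(len(ZONES)):
                cx, cy = gt.zone_centers_px[i, zi].astype(int)
                assert seq.frames[k, cy, cx] == gt.zone_temps_c[i, zi]

    def test_noise_std_matches_thermal_sensitivity(self):
        # per-pixel std over static frames ~ 0.04 degC within 10%
        cfg = make_cfg(excursion_amplitude_px=0.0, duration_s=5.0,
                       zone_trends_c_per_min={})
        gt = generate_kinematics(cfg)
        seq = render_thermal(cfg, gt)  # 100 frames
        stds = seq.frames.std(axis=0, ddof=1)
        assert abs(stds.mean() - cfg.thermal_noise_c) < 0.1 * cfg.thermal_noise_c

    def test_determinism_bit_identical(self):
        cfg = make_cfg(seed=9, duration_s=5.0)
        gt1 = generate_kinematics(cfg)
        gt2 = generate_kinematics(make_cfg(seed=9, duration_s=5.0))
        assert np.array_equal(gt1.zone_temps_c, gt2.zone_temps_c)
        s1 = render_thermal(cfg, gt1, indices=[0, 50])
        s2 = render_thermal(cfg, gt2, indices=[0, 50])
        assert np.array_equal(s1.frames, s2.frames)
        t1 = simulate_tracker(cfg, gt1)
        t2 = simulate_tracker(cfg, gt2)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(
            t1.likelihood, t2.likelihood)
        c1 = simulate_loadcells(cfg, gt1)
        c2 = simulate_loadcells(cfg, gt2)
        assert np.array_equal(c1.tl, c2.tl)

    def test_noise_stream_keyed_by_frame_index(self):
        cfg = make_cfg(duration_s=5.0)
        gt = generate_kinematics(cfg)
        a = render_thermal(cfg, gt, indices=[10, 20])
        b = render_thermal(cfg, gt, indices=[20])
        assert np.array_equal(a.frames[1], b.frames[0])


class TestTracker:
    def test_noiseless_tracker_is_exact(self):
        cfg = make_noiseless_cfg(duration_s=5.0)
        gt = generate_kinematics(cfg)
        track = simulate_tracker(cfg, gt)
        assert np.array_equal(track.x, gt.zone_centers_px[:, :, 0])
        assert np.array_equal(track.y, gt.zone_centers_px[:, :, 1])

    def test_rms_error_calibrated(self):
        # >= 10 000 samples: empirical radial RMS within 5% of 9.3 px
        cfg = make_cfg(duration_s=60.0, tracker_rms_px=9.3, seed=4)
        gt = generate_kinematics(cfg)
        track = simulate_tracker(cfg, gt)
        err2 = ((track.x - gt.zone_centers_px[:, :, 0]) ** 2
                + (track.y - gt.zone_centers_px[:, :, 1]) ** 2)
        assert err2.size >= 10_000
        rms = float(np.sqrt(err2.mean()))
        assert abs(rms - 9.3) < 0.05 * 9.3

    def test_dropout_fraction_binomial(self):
        cfg = make_cfg(duration_s=60.0, dropout_prob=0.1, seed=6)
        gt = generate_kinematics(cfg)
        track = simulate_tracker(cfg, gt)
        frac = float((track.likelihood < 0.5).mean())
        n = track.likelihood.size
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) < 4 * se

    def test_mean_likelihood_near_configured(self):
        cfg = make_cfg(duration_s=60.0, dropout_prob=0.0, seed=6)
        track = simulate_tracker(cfg, generate_kinematics(cfg))
        assert track.likelihood.mean() == pytest.approx(0.99, abs=0.005)


class TestLoadCells:
    def test_corner_sum_conserves_total_pre_noise(self):
        cfg = make_noiseless_cfg(left_share=0.53)
        gt = generate_kinematics(cfg)
        cells = simulate_loadcells(cfg, gt)
        total = total_weight(cells)
        standing = gt.phase == "standing"
        # at the excursion peak the full body mass is on the board (the
        # sample grid may fall just short of the exact cosine peak)
        assert total.max() == pytest.approx(cfg.body_mass_kg, rel=1e-3)
        # left share holds at every sample by construction
        left = (cells.tl + cells.bl)[standing] / total[standing]
        np.testing.assert_allclose(left, 0.53, atol=1e-12)

    def test_symmetric_split_gives_equal_pairs(self):
        cfg = make_noiseless_cfg(left_share=0.5, rear_share=0.5)
        gt = generate_kinematics(cfg)
        cells = simulate_loadcells(cfg, gt)
        np.testing.assert_allclose(cells.tl, cells.tr, atol=1e-12)
        np.testing.assert_allclose(cells.tl, cells.bl, atol=1e-12)

    def test_sitting_total_near_zero(self):
        cfg = make_noiseless_cfg()
        gt = generate_kinematics(cfg)
        cells = simulate_loadcells(cfg, gt)
        sitting = gt.phase == "sitting"
        assert total_weight(cells)[sitting].min() >= 0
        assert total_weight(cells)[sitting].min() < 0.15 * cfg.body_mass_kg


def test_ground_truth_sufficient_for_recovery(small_run):
    """The ground truth alone predicts every downstream observable."""
    cfg, gt, track, cells, idx, seq = small_run
    # tracker == centers (noiseless), loadcells from phase + shares
    assert np.array_equal(track.x, gt.zone_centers_px[:, :, 0])
    standing = gt.phase == "standing"
    total = total_weight(cells)
    assert total[standing].max() <= cfg.body_mass_kg + 1e-9
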