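"""Phantom construction, cohort generation and forward simulators."""

import numpy as np
import pytest

from hepaflow.phantom import (CohortConfig, build_cohort, ir_signal,
                              make_phantom, simulate_fair_series,
                              simulate_pc_cine,
                              simulate_respiration_and_timetable,
                              t1_slice_selective_from_perfusion, wrap_phase)


class TestSliceSelectiveT1:
    @pytest.mark.parametrize("t1g, perf, expected", [
        (1256.0, 0.0, 1256.0),                       # zero perfusion: unchanged
        (1256.0, 140.0, 1256.0 / (1 + 140 / 3000)),  # 1200.0
        (1256.0, 316.0, 1256.0 / (1 + 316 / 3000)),  # 1136.3, sham group mean
    ])
    def test_known_values(self, t1g, perf, expected):
        assert t1_slice_selective_from_perfusion(t1g, perf) == pytest.approx(
            expected, rel=1e-12)

    def test_round_trips_through_perfusion_map(self):
        from hepaflow.perfusion import perfusion_map

        p_true = np.linspace(0.0, 2000.0, 41)
        t1_ss = t1_slice_selective_from_perfusion(1256.0, p_true)
        pm = perfusion_map(np.full_like(t1_ss, 1256.0), t1_ss)
        assert pm.valid.all()
        np.testing.assert_allclose(pm.values, p_true, rtol=1e-10, atol=1e-9)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ValueError):
            t1_slice_selective_from_perfusion(0.0, 100.0)


class TestCohort:
    def test_zero_variance_draws_hit_means_exactly(self):
        cfg = CohortConfig(
            n_sham=4, n_bdl=3,
            sham_perfusion_sd=0, bdl_perfusion_sd=0, sham_t1_sd=0, bdl_t1_sd=0,
            sham_weight_sd=0, bdl_weight_sd=0,
            sham_lps_perfusion_shift_sd=0, bdl_lps_perfusion_shift_sd=0,
            sham_lps_t1_shift_sd=0, bdl_lps_t1_shift_sd=0, tlbf_offset_sd=0)
        cohort = build_cohort(cfg, seed=3, matrix=32)
        sham = [p for p in cohort if p.cohort == "sham"]
        assert len(cohort) == 7
        assert all(p.mean_perfusion_true == 316.0 for p in sham)
        assert all(p.tissue_t1_ms["liver"] == 1256.0 for p in sham)

    def test_reproducible_under_fixed_seed(self):
        a = build_cohort(CohortConfig(), seed=11, matrix=32)
        b = build_cohort(CohortConfig(), seed=11, matrix=32)
        for pa, pb in zip(a, b):
            assert pa.mean_perfusion_true == pb.mean_perfusion_true
            assert pa.liver_weight_g == pb.liver_weight_g
            assert pa.lost_post_lps == pb.lost_post_lps

    def test_monte_carlo_group_means(self):
        # sample means of the generated parameters match the configured
        # distributions within 3 SEM at large n
        cfg = CohortConfig(n_sham=1, n_bdl=1)
        n = 4000
        cohort = build_cohort(CohortConfig(n_sham=n, n_bdl=1), seed=5, matrix=16)
        perf = np.array([p.mean_perfusion_true for p in cohort
                         if p.cohort == "sham"])
        t1 = np.array([p.tissue_t1_ms["liver"] for p in cohort
                       if p.cohort == "sham"])
        assert abs(perf.mean() - cfg.sham_perfusion_mean) < \
            3 * cfg.sham_perfusion_sd / np.sqrt(n) + 0.7  # + clamp-at-zero bias
        assert abs(t1.mean() - cfg.sham_t1_mean) < 3 * cfg.sham_t1_sd / np.sqrt(n)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            build_cohort(CohortConfig(n_sham=0), seed=0)


class TestFairSeries:
    def test_null_point_of_recovery_curve(self):
        # with perfect inversion (alpha = 2) the signal crosses zero at
        # TI = T1* ln 2, and T1* equals the tissue T1
        assert ir_signal(1000.0, 2.0, 540.0, 540.0 * np.log(2)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_noiseless_roundtrip_recovers_t1(self, phantom64):
        from hepaflow.t1fit import fit_t1_map

        series = simulate_fair_series(phantom64, "global")
        maps = fit_t1_map(series, smooth=False, mask=phantom64.liver_mask)
        truth = phantom64.true_t1_map("global")
        err = np.abs(maps.t1[phantom64.liver_mask] /
                     truth[phantom64.liver_mask] - 1)
        assert maps.valid[phantom64.liver_mask].all()
        assert err.max() < 1e-6

    def test_zero_perfusion_makes_modes_identical(self):
        ph = make_phantom(matrix=32, perfusion_ml_min_100g=0.0)
        a = simulate_fair_series(ph, "global", noise_sd=5.0, seed=9)
        b = simulate_fair_series(ph, "slice_selective", noise_sd=5.0, seed=9)
        np.testing.assert_array_equal(a.images, b.images)

    def test_unknown_mode_rejected(self, phantom64):
        with pytest.raises(ValueError):
            simulate_fair_series(phantom64, "sagittal")

    def test_deterministic_under_seed(self, phantom64):
        a = simulate_fair_series(phantom64, "global", noise_sd=10.0, seed=4)
        b = simulate_fair_series(phantom64, "global", noise_sd=10.0, seed=4)
        np.testing.assert_array_equal(a.images, b.images)

    def test_rician_noise_is_nonnegative(self, phantom64):
        s = simulate_fair_series(phantom64, "global", noise_sd=10.0, seed=4,
                                 noise_model="rician")
        assert (s.images >= 0).all()


class TestPcCine:
    def test_no_pulsatility_gives_identical_frames(self):
        ph = make_phantom(matrix=32, pulsatility_fraction=0.0)
        cine = simulate_pc_cine(ph, "infra_IVC")
        assert np.ptp(cine.frames, axis=0).max() == 0.0

    def test_peak_phase_below_venc_is_unwrapped(self):
        ph = make_phantom(matrix=32, infra_peak_velocity_cm_s=20.0,
                          pulsatility_fraction=0.0)
        cine = simulate_pc_cine(ph, "infra_IVC", venc_cm_s=33.0)
        # peak phase 20*pi/33 ~ 1.904 rad; discrete pixel centres miss the
        # exact vessel axis, so allow the sub-pixel sampling shortfall
        assert cine.frames.max() == pytest.approx(20 * np.pi / 33, rel=0.02)
        assert cine.frames.max() < np.pi  # no wrap
        assert cine.frames.min() >= 0.0

    def test_above_venc_velocity_wraps_and_flags(self):
        from hepaflow.pcflow import circular_roi, decode_velocity

        ph = make_phantom(matrix=32, infra_peak_velocity_cm_s=40.0,
                          pulsatility_fraction=0.0)
        cine = simulate_pc_cine(ph, "infra_IVC", venc_cm_s=33.0)
        roi = circular_roi(cine.frames.shape[1:], cine.vessel_centre_px,
                           cine.vessel_radius_px)
        assert (cine.frames[0][roi] < 0).any()  # wrapped phase present
        _, aliased = decode_velocity(cine.frames[0], 33.0, vessel_mask=roi)
        assert aliased

    def test_wrap_phase_range_and_identity(self):
        x = np.linspace(-10, 10, 1001)
        w = wrap_phase(x)
        assert (w > -np.pi).all() and (w <= np.pi).all()
        inside = np.linspace(-np.pi + 1e-9, np.pi, 101)
        np.testing.assert_allclose(wrap_phase(inside), inside, atol=1e-12)

    def test_invalid_venc_and_vessel(self, phantom64):
        with pytest.raises(ValueError):
            simulate_pc_cine(phantom64, "infra_IVC", venc_cm_s=-1.0)
        with pytest.raises(ValueError):
            simulate_pc_cine(phantom64, "aorta")


class TestRespirationTimetable:
    def test_fully_quiescent_breathing_never_flags(self):
        ph = make_phantom(matrix=32, quiescent_fraction=1.0)
        resp, table = simulate_respiration_and_timetable(ph, seed=2)
        assert resp.is_quiescent(table.lines["time_s"].to_numpy()).all()

    def test_long_segments_overrun_quiescent_windows(self):
        ph = make_phantom(matrix=32, resp_period_s=1.0, quiescent_fraction=0.4)
        resp, table = simulate_respiration_and_timetable(ph, seed=2)
        q = resp.is_quiescent(table.lines["time_s"].to_numpy())
        assert (~q).any()

    def test_timetable_covers_all_tis_and_rows(self):
        ph = make_phantom(matrix=32)
        _, table = simulate_respiration_and_timetable(ph, seed=0)
        df = table.lines
        assert set(df["ti_index"]) == set(range(50))
        assert set(df["kspace_row"]) == set(range(32))
        assert len(df) == 50 * 32

    def test_deterministic_under_seed(self):
        ph = make_phantom(matrix=32)
        _, a = simulate_respiration_and_timetable(ph, seed=6)
        _, b = simulate_respiration_and_timetable(ph, seed=6)
        assert a.lines.equals(b.lines)


def test_phantom_validate_rejects_bad_parameters():
    with pytest.raises(ValueError):
        make_phantom(matrix=32, alpha=2.5)
    with pytest.raises(ValueError):
        make_phantom(matrix=32, liver_weight_g=-1.0)
    with pytest.raises(ValueError):
        make_phantom(matrix=32, quiescent_fraction=0.0)
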