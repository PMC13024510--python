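"""Radial profile estimation, gain construction, and flat-field correction."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echocorrect import (
    AnnulusBinning,
    ImageSlice,
    PhantomSpec,
    RadialCalibration,
    SensitivityModel,
    annular_average_profile,
    apply_radial_correction,
    build_radial_gain,
    make_calibration_phantom,
    radial_distance_map,
    smooth_and_normalize,
)


class TestRadialDistanceMap:
    def test_center_and_345_triangle(self):
        rho = radial_distance_map((33, 33), (16.0, 16.0))
        assert rho[16, 16] == 0.0
        assert rho[16 + 4, 16 + 3] == pytest.approx(5.0)

    def test_rotation_invariance(self):
        rho = radial_distance_map((33, 33), (16.0, 16.0))
        np.testing.assert_allclose(rho, np.rot90(rho), rtol=1e-12)


class TestAnnularBinning:
    def test_half_open_interval_convention(self):
        # a pixel exactly at ρ+Δ belongs to the NEXT bin
        b = AnnulusBinning(delta=1.0)  # bins centred at 0, 2, 4 …
        assert b.bin_index(np.array([0.999]))[0] == 0
        assert b.bin_index(np.array([1.0]))[0] == 1

    def test_bins_tile_without_gaps(self):
        b = AnnulusBinning(delta=0.5)
        rho = np.linspace(0, 50, 100001)
        idx = b.bin_index(rho)
        assert np.all(np.diff(idx) >= 0)
        assert set(np.unique(idx)) == set(range(idx.max() + 1))

    def test_delta_must_be_positive(self):
        with pytest.raises(ValueError):
            AnnulusBinning(delta=0.0)


class TestAnnularAverage:
    def test_constant_image(self, small_spec):
        img, _ = make_calibration_phantom(small_spec)
        profile = annular_average_profile(img)
        np.testing.assert_allclose(profile.s_raw, 1.0)

    def test_radius_valued_image_brute_force(self):
        rho = radial_distance_map((65, 65), (32.0, 32.0))
        img = ImageSlice(rho, center_xy=(32.0, 32.0))
        binning = AnnulusBinning(delta=0.5)
        profile = annular_average_profile(img, binning)
        # independent brute-force annulus means
        mask = img.fov_mask
        for r, s in zip(profile.radii, profile.s_raw):
            sel = mask & (rho >= r - 0.5) & (rho < r + 0.5)
            assert s == pytest.approx(rho[sel].mean())
            assert abs(s - r) <= 0.5

    def test_counts_positive_for_retained_bins(self, calibration_06):
        img, _ = calibration_06
        profile = annular_average_profile(img)
        assert np.all(profile.counts > 0)

    def test_db_input_rejected_with_hint(self, calibration_06):
        img, _ = calibration_06
        with pytest.raises(ValueError, match="to_linear"):
            annular_average_profile(img.to_db())

    def test_empty_fov_rejected(self):
        img = ImageSlice(np.ones((9, 9)), fov_mask=np.zeros((9, 9), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            annular_average_profile(img)


class TestSmoothAndNormalize:
    def test_cubic_polynomial_reproduced_exactly(self):
        radii = np.arange(80, dtype=np.float64)
        s_raw = 2.0 + 0.1 * radii - 2e-3 * radii**2 + 5e-6 * radii**3
        from echocorrect.radial import RadialProfile

        profile = RadialProfile(radii=radii, s_raw=s_raw, counts=np.ones(80))
        out = smooth_and_normalize(profile, window=33, order=3)
        np.testing.assert_allclose(out.s_smooth, s_raw, rtol=1e-9)

    def test_constant_profile_normalises_to_one(self):
        from echocorrect.radial import RadialProfile

        profile = RadialProfile(radii=np.arange(50.0), s_raw=np.full(50, 5.0), counts=np.ones(50))
        out = smooth_and_normalize(profile)
        np.testing.assert_allclose(out.s_norm, 1.0)
        assert out.s_norm[0] == 1.0

    def test_noise_variance_reduced(self):
        # Monte-Carlo: smoothing must reduce the deviation from the true curve
        from echocorrect.radial import RadialProfile

        radii = np.arange(120, dtype=np.float64)
        true = 1.0 - 0.5 * (radii / 120.0) ** 2
        rng = np.random.default_rng(5)
        raw_var, smooth_var = 0.0, 0.0
        for _ in range(100):
            noisy = true + rng.normal(0, 0.05, radii.size)
            profile = RadialProfile(radii=radii, s_raw=noisy, counts=np.ones_like(radii))
            out = smooth_and_normalize(profile, window=33, order=3)
            raw_var += np.var(noisy - true)
            smooth_var += np.var(out.s_smooth - true)
        assert smooth_var < raw_var

    def test_window_autoshrink_on_short_profiles(self):
        from echocorrect.radial import RadialProfile

        profile = RadialProfile(radii=np.arange(11.0), s_raw=np.ones(11), counts=np.ones(11))
        out = smooth_and_normalize(profile, window=33, order=3)
        assert out.meta["sg_window"] == 11


class TestBuildRadialGain:
    @staticmethod
    def _profile(s_norm):
        from echocorrect.radial import RadialProfile

        n = len(s_norm)
        return RadialProfile(
            radii=np.arange(n, dtype=np.float64),
            s_raw=np.asarray(s_norm, dtype=np.float64),
            counts=np.ones(n),
            s_smooth=np.asarray(s_norm, dtype=np.float64),
            s_norm=np.asarray(s_norm, dtype=np.float64),
        )

    def test_unit_profile_unit_gain(self):
        gain = build_radial_gain(self._profile(np.ones(100)), epsilon=0.0, r_eff=95.0)
        np.testing.assert_allclose(gain(np.linspace(0, 95, 50)), 1.0)

    def test_reciprocal_identity_to_machine_precision(self):
        s = np.linspace(1.0, 0.3, 100)
        gain = build_radial_gain(self._profile(s), epsilon=1e-3)
        np.testing.assert_allclose(gain.gain_curve * (s + 1e-3), 1.0, rtol=1e-14)

    def test_clipping_at_g_max(self):
        s = np.full(100, 0.25)
        s[0] = 1.0
        gain = build_radial_gain(self._profile(s), epsilon=0.0, g_max=2.0, r_eff=95.0)
        assert gain.gain_curve[50] == pytest.approx(4.0)
        assert gain.gain_clipped[50] == pytest.approx(2.0)
        assert gain(np.array([50.0]))[0] == pytest.approx(2.0)

    def test_masked_to_zero_beyond_r_eff(self):
        gain = build_radial_gain(self._profile(np.ones(100)), r_eff=80.0)
        assert np.all(gain(np.array([80.5, 95.0, 200.0])) == 0.0)
        assert np.all(gain.gain_clipped[gain.radii > 80.0] == 0.0)

    @given(st.floats(min_value=0.0, max_value=0.5), st.floats(min_value=0.0, max_value=0.5))
    def test_raising_epsilon_never_raises_gain(self, eps1, eps2):
        lo, hi = sorted((eps1, eps2))
        s = np.linspace(1.0, 0.2, 60)
        g_lo = build_radial_gain(self._profile(s), epsilon=lo, g_max=10.0)
        g_hi = build_radial_gain(self._profile(s), epsilon=hi, g_max=10.0)
        assert np.all(g_hi.gain_curve <= g_lo.gain_curve + 1e-15)

    def test_invalid_profile_rejected(self):
        s = np.linspace(1.0, -0.5, 60)
        with pytest.raises(ValueError, match="invalid"):
            build_radial_gain(self._profile(s), epsilon=0.0)


class TestApplyCorrection:
    def test_unit_gain_is_identity_inside_r_eff(self, calibration_06):
        img, _ = calibration_06
        flat, _ = make_calibration_phantom(PhantomSpec(fov_radius_px=64.0))
        result = RadialCalibration(flat).fit(epsilon=0.0, r_eff=60.0)
        out = result.apply(img)
        rho = img.radius_map()
        inner = img.fov_mask & (rho <= 60.0 - 1.0)
        np.testing.assert_allclose(out.pixels[inner], img.pixels[inner], rtol=1e-12)

    def test_self_correction_flattens_profile(self, calibration_06):
        img, _ = calibration_06
        result = RadialCalibration(img).fit(epsilon=1e-3, g_max=2.0, r_eff=0.95 * 64)
        corrected = result.apply(img)
        profile = annular_average_profile(corrected, r_max=0.9 * 64)
        vals = profile.s_raw[profile.counts > 4]
        assert np.max(np.abs(vals - vals.mean())) / vals.mean() < 0.02

    def test_scale_invariance(self, calibration_06):
        img, _ = calibration_06
        c = 7.3
        scaled = img.copy()
        scaled.pixels = img.pixels * c
        res = RadialCalibration(img).fit(g_max=2.0)
        res_scaled = RadialCalibration(scaled).fit(g_max=2.0)
        out = res.apply(img)
        out_scaled = res_scaled.apply(scaled)
        np.testing.assert_allclose(out_scaled.pixels, c * out.pixels, rtol=1e-9)

    def test_mask_conservation(self, calibration_06):
        img, _ = calibration_06
        result = RadialCalibration(img).fit(r_eff=50.0)
        out = result.apply(img)
        assert (out.pixels != 0).sum() <= img.fov_mask.sum()
        assert out.fov_mask.sum() <= img.fov_mask.sum()

    def test_idempotence_on_flat_field(self, calibration_06):
        img, _ = calibration_06
        first = RadialCalibration(img).fit(epsilon=1e-3, g_max=2.0, r_eff=0.95 * 64)
        once = first.apply(img)
        second = RadialCalibration(once).fit(epsilon=1e-3, g_max=2.0, r_eff=0.95 * 64)
        twice = second.apply(once)
        unclipped = once.fov_mask & (first.gain(once.radius_map()) < 2.0) & (once.pixels > 0)
        rel = np.abs(twice.pixels[unclipped] - once.pixels[unclipped]) / once.pixels[unclipped]
        assert np.max(rel) < 0.005

    def test_geometry_mismatch_rejected(self, calibration_06):
        img, _ = calibration_06
        result = RadialCalibration(img).fit()
        shifted = ImageSlice(img.pixels.copy(), center_xy=(10.0, 10.0))
        with pytest.raises(ValueError, match="centre"):
            result.apply(shifted)

    def test_db_round_trip_application(self, calibration_06):
        img, _ = calibration_06
        result = RadialCalibration(img).fit(g_max=2.0, r_eff=0.9 * 64)
        lin = result.apply(img)
        db = result.apply(img.to_db())
        inner = lin.fov_mask & (lin.pixels > 1e-3)
        np.testing.assert_allclose(db.to_linear().pixels[inner], lin.pixels[inner], rtol=1e-6)


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "sens",
        [
            SensitivityModel.gaussian(0.5),
            SensitivityModel.dmas(np.linspace(0, 1, 21), np.linspace(2.0, 1.2, 21)),
        ],
        ids=["gaussian", "dmas"],
    )
    def test_estimated_profile_matches_true_field(self, sens):
        spec = PhantomSpec(fov_radius_px=100.0)
        r_eff = 0.95 * 100.0
        img, gt = make_calibration_phantom(spec, sens, sens_edge_radius=r_eff)
        result = RadialCalibration(img).fit(r_eff=r_eff)
        profile = result.profile
        sel = profile.radii <= 0.9 * r_eff
        true = sens(profile.radii[sel] / r_eff)
        rel = np.abs(profile.s_norm[sel] - true) / true
        assert np.max(rel) < 0.02

    def test_summary_reports_parameters(self, calibration_06):
        img, _ = calibration_06
        result = RadialCalibration(img).fit(epsilon=1e-3, g_max=2.0)
        text = result.summary()
        assert "G_max" in text and "R_eff" in text and "epsilon" in text
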