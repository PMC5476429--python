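import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fibsem_phys import image_quality as IQ


@pytest.fixture(scope="module")
def texture():
    return np.random.default_rng(7).normal(0.0, 1.0, (64, 64))


class TestFocusIndex:
    def test_constant_image_is_zero(self):
        assert IQ.focus_index(np.full((32, 32), 7.0)) == pytest.approx(0.0,
                                                                       abs=1e-20)

    def test_offset_invariance_and_quadratic_scaling(self, texture):
        base = IQ.focus_index(texture)
        assert IQ.focus_index(texture + 13.0) == pytest.approx(base, rel=1e-9)
        assert IQ.focus_index(3.0 * texture) == pytest.approx(9.0 * base,
                                                              rel=1e-9)

    def test_blur_reduces_sharpness(self, texture):
        blurred = ndimage.gaussian_filter(texture, 2.0)
        assert IQ.focus_index(texture) > IQ.focus_index(blurred)

    def test_parameter_validation(self, texture):
        with pytest.raises(ValueError):
            IQ.focus_index(texture, s1=4, s2=1)
        with pytest.raises(ValueError):
            IQ.focus_index(np.ones((4, 4)))


class TestFitOptimum:
    def test_symmetric_sweep(self):
        sweep = IQ.FocusSweep([-2, 0, 2], [2, 6, 2])
        assert IQ.fit_optimum(sweep) == pytest.approx(0.0, abs=1e-12)

    def test_three_point_parabola(self):
        sweep = IQ.FocusSweep([-2, 0, 2], [1, 5, 3])
        assert IQ.fit_optimum(sweep) == pytest.approx(1 / 3, rel=1e-9)

    @given(st.floats(-5, 5), st.floats(0.1, 10), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_exact_vertex_recovery(self, vertex, curvature, offset):
        xs = np.array([-3.0, -1.0, 0.5, 2.0, 4.0])
        ys = offset - curvature * (xs - vertex) ** 2
        sweep = IQ.FocusSweep(xs, ys)
        assert IQ.fit_optimum(sweep) == pytest.approx(vertex, abs=1e-6)

    def test_clamping_with_warning(self):
        sweep = IQ.FocusSweep([-2, 0, 2], [1, 5, 3], bounds=(-0.2, 0.2))
        with pytest.warns(UserWarning):
            assert IQ.fit_optimum(sweep) == 0.2

    def test_convex_fit_rejected(self):
        sweep = IQ.FocusSweep([-2, 0, 2], [5, 1, 5])
        with pytest.raises(IQ.NoOptimumError):
            IQ.fit_optimum(sweep)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            IQ.FocusSweep([0, 1], [1, 2])


class TestAutoOptimize:
    def test_unknown_channel(self):
        with pytest.raises(ValueError):
            IQ.auto_optimize("coil", IQ.FocusSweep([-1, 0, 1], [1, 2, 1]))

    def test_noiseless_quadratic_single_iteration(self):
        # when the FI response really is quadratic, one sweep is exact
        xs = np.linspace(-1.5, 1.5, 5)
        sweep = IQ.FocusSweep(xs, 5.0 - 2.0 * (xs - 0.7) ** 2)
        assert IQ.auto_optimize("focus", sweep) == pytest.approx(0.7, abs=1e-9)

    def test_iterated_recovery_of_focus_and_stigmation(self):
        imager = IQ.SimulatedImager(true_focus=0.4, true_stig_x=-0.2, seed=3)
        final = imager.optimize(("focus", "stig_x"), iterations=3)
        assert final["focus"] == pytest.approx(0.4, abs=0.05)
        assert final["stig_x"] == pytest.approx(-0.2, abs=0.05)

    def test_already_optimal_is_fixed_point(self):
        imager = IQ.SimulatedImager(seed=4)
        final = imager.optimize(("focus",), iterations=1)
        assert final["focus"] == pytest.approx(0.0, abs=0.05)


class TestCalibration:
    def test_electrons_per_pixel(self):
        assert IQ.electrons_per_pixel(1.0, 2.0) == pytest.approx(12_483, abs=1)
        assert IQ.electrons_per_pixel(0.0, 2.0) == 0.0
        assert IQ.electrons_per_pixel(4.0, 3.0) == pytest.approx(
            6 * IQ.electrons_per_pixel(1.0, 2.0))

    def test_gain_from_total_reflection_fixture(self):
        bg = np.full((16, 16), 100.0)
        fb = np.full((16, 16), 1100.0)
        model = IQ.calibrate(bg, fb, 1.0, 2.0)
        assert model.offset_grey == 100.0
        assert model.grey_per_electron == pytest.approx(0.0801, abs=2e-4)

    def test_round_trip(self):
        bg = np.full((8, 8), 100.0)
        fb = np.full((8, 8), 1100.0)
        model = IQ.calibrate(bg, fb, 1.0, 2.0)
        electrons = IQ.grey_to_electrons(fb, model)
        assert np.mean(electrons) == pytest.approx(
            IQ.electrons_per_pixel(1.0, 2.0), rel=1e-9)

    def test_zero_gain_rejected(self):
        img = np.full((8, 8), 100.0)
        with pytest.raises(IQ.CalibrationError):
            IQ.calibrate(img, img, 1.0, 2.0)


class TestSnrContrast:
    def test_membrane_cytosol_reference_counts(self):
        snr, contrast = IQ.snr_contrast(720, 630)
        assert snr == pytest.approx(3.464, abs=0.001)
        assert contrast == pytest.approx(0.1333, abs=0.0005)

    def test_equal_counts(self):
        assert IQ.snr_contrast(500, 500) == (0.0, 0.0)

    def test_homogeneity(self):
        snr1, c1 = IQ.snr_contrast(720, 630)
        snr4, c4 = IQ.snr_contrast(4 * 720, 4 * 630)
        assert snr4 == pytest.approx(2 * snr1)
        assert c4 == pytest.approx(c1)

    def test_sign_preserved_and_zero_rejected(self):
        snr, c = IQ.snr_contrast(630, 720)
        assert snr < 0 and c < 0
        with pytest.raises(ZeroDivisionError):
            IQ.snr_contrast(0, 0)


class TestEstimateLevels:
    def test_two_level_fixture(self):
        rng = np.random.default_rng(11)
        img = np.where(rng.random((128, 128)) < 0.3,
                       rng.normal(700, 10, (128, 128)),
                       rng.normal(600, 10, (128, 128)))
        est = IQ.estimate_levels(img, 700.0, 600.0)
        assert (est.n_m, est.n_c) == (700.0, 600.0)
        # roughly half the membrane pixels sit above the membrane level
        assert est.membrane_coverage == pytest.approx(0.3 / 2, abs=0.05)

    def test_threshold_outside_range(self):
        img = np.zeros((8, 8))
        with pytest.raises(ValueError):
            IQ.estimate_levels(img, 10.0, 0.0)

    def test_swapped_thresholds_invert_contrast(self):
        rng = np.random.default_rng(12)
        img = rng.normal(650, 50, (32, 32))
        est = IQ.estimate_levels(img, 600.0, 700.0)
        snr, c = IQ.snr_contrast(est.n_m, est.n_c)
        assert c < 0


class TestShotNoise:
    def test_poisson_rms(self):
        img = np.random.default_rng(13).poisson(400, (256, 256)).astype(float)
        assert IQ.shot_noise_estimate(img) == pytest.approx(20.0, rel=0.05)

    def test_constant_image(self):
        assert IQ.shot_noise_estimate(np.full((32, 32), 5.0)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_sqrt_scaling_across_two_decades(self):
        rng = np.random.default_rng(14)
        lams = np.array([100.0, 400.0, 1600.0])
        ests = [IQ.shot_noise_estimate(rng.poisson(lam, (256, 256)).astype(float))
                for lam in lams]
        slope = np.polyfit(np.log(lams), np.log(ests), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            IQ.shot_noise_estimate(np.ones((2, 2)))


class TestStreakFilter:
    def test_notched_sinusoid_suppressed(self):
        n, f0 = 128, 0.125
        img = 100 + 10 * np.sin(2 * np.pi * f0 * np.arange(n))[None, :] \
            * np.ones((n, 1))
        out = IQ.streak_filter(img, [(-0.01, 0.01, f0 - 0.02, f0 + 0.02)])
        assert np.ptp(out) / 2 < 0.1  # residual < 1% of the 10-unit amplitude
        assert np.mean(out) == pytest.approx(100.0, rel=1e-6)

    def test_empty_band_set_is_identity(self):
        img = np.random.default_rng(15).normal(size=(32, 32))
        np.testing.assert_allclose(IQ.streak_filter(img, []), img, atol=1e-12)

    def test_dc_band_rejected(self):
        with pytest.raises(ValueError):
            IQ.streak_filter(np.ones((16, 16)), [(-0.1, 0.1, -0.1, 0.1)])

    def test_mean_preserved_under_aggressive_notching(self):
        img = np.random.default_rng(16).normal(50.0, 5.0, (64, 64))
        out = IQ.streak_filter(img, [(-0.02, 0.02, 0.05, 0.45)])
        assert np.mean(out) == pytest.approx(np.mean(img), rel=1e-6)


class TestImageGridIO:
    def test_tiff_round_trip(self, tmp_path):
        grid = IQ.ImageGrid(np.arange(64.0).reshape(8, 8), pixel_size=4.0,
                            units="electrons")
        path = tmp_path / "img.tiff"
        grid.to_tiff(path)
        back = IQ.ImageGrid.from_tiff(path)
        np.testing.assert_allclose(back.values, grid.values)
        assert back.pixel_size == 4.0 and back.units == "electrons"

    def test_hdf5_round_trip(self, tmp_path):
        grid = IQ.ImageGrid(np.ones((4, 8, 8)), pixel_size=8.0,
                            units="electrons", z_step=2.0)
        path = tmp_path / "stack.h5"
        grid.to_hdf5(path)
        back = IQ.ImageGrid.from_hdf5(path)
        assert back.values.shape == (4, 8, 8)
        assert back.z_step == 2.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            IQ.ImageGrid(np.array([[1.0, np.nan]]))
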