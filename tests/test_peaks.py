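"""Peak measurement, the cylinder transform and Bessel compensation."""

import numpy as np
import pytest
from scipy.special import j1

import fibrilsaxs as fs
from fibrilsaxs.errors import CompensationError, PeakNotFoundError, ValidationError
from fibrilsaxs.profiles import RadialProfile

CAL = fs.make_calibration(60.0, 67.0)  # 67 nm first order at 60 px


def gaussian_profile(centre=120.0, sigma=5.0, height=200.0, r_max=400):
    r = np.arange(0.0, r_max + 1.0)
    return RadialProfile(r, height * np.exp(-((r - centre) ** 2) / (2 * sigma**2)),
                         np.ones_like(r, int))


def brute_force_shape_sq(x):
    return (2.0 * j1(x) / x) ** 2


class TestFindNearestPeak:
    def test_gaussian_position_and_fwhm(self):
        peak = fs.find_nearest_peak(gaussian_profile(), guess_px=112, window_px=15)
        assert peak.position_px == pytest.approx(120.0, abs=0.1)
        fwhm = 2 * np.sqrt(2 * np.log(2)) * 5.0  # 11.774
        assert peak.hhw_px == pytest.approx(fwhm, rel=0.01)
        assert peak.left_px < peak.position_px < peak.right_px

    def test_guess_at_maximum_returns_it(self):
        peak = fs.find_nearest_peak(gaussian_profile(), guess_px=120, window_px=15)
        assert peak.position_px == pytest.approx(120.0, abs=1e-6)
        assert peak.height == pytest.approx(200.0, rel=1e-6)

    def test_nearest_not_highest(self):
        r = np.arange(0.0, 200.0)
        y = (50 * np.exp(-((r - 80) ** 2) / 18)
             + 500 * np.exp(-((r - 95) ** 2) / 18))
        prof = RadialProfile(r, y, np.ones_like(r, int))
        peak = fs.find_nearest_peak(prof, guess_px=82, window_px=15)
        assert peak.position_px == pytest.approx(80.0, abs=0.5)

    def test_no_maximum_raises(self):
        r = np.arange(0.0, 100.0)
        prof = RadialProfile(r, -r, np.ones_like(r, int))  # monotone
        with pytest.raises(PeakNotFoundError):
            fs.find_nearest_peak(prof, guess_px=50, window_px=10)

    def test_hhw_undefined_when_crossing_beyond_edge(self):
        prof = gaussian_profile(centre=398.0, sigma=6.0)
        peak = fs.find_nearest_peak(prof, guess_px=397, window_px=5)
        assert peak.hhw_px is None
        assert fs.order_parameter(peak) is None


class TestOrderParameter:
    def test_quotient(self):
        peak = fs.PeakMeasurement(120.0, 200.0, 11.774, 114.113, 125.887)
        assert fs.order_parameter(peak) == pytest.approx(200.0 / 11.774)
        assert fs.order_parameter(peak) == pytest.approx(16.987, abs=1e-3)

    def test_scaling_and_monotonicity(self):
        prof = gaussian_profile()
        doubled = RadialProfile(prof.radius_px, 2 * prof.intensity, prof.n_valid)
        p1 = fs.find_nearest_peak(prof, 120, 15)
        p2 = fs.find_nearest_peak(doubled, 120, 15)
        assert fs.order_parameter(p2) == pytest.approx(2 * fs.order_parameter(p1), rel=1e-9)
        broader = fs.find_nearest_peak(gaussian_profile(sigma=8.0), 120, 15)
        assert fs.order_parameter(broader) < fs.order_parameter(p1)


class TestCylinderTransform:
    def test_value_at_zero_is_amplitude(self):
        model = fs.CylinderTransform(r_nm=19.1, amplitude=7.0)
        assert model.evaluate(0.0) == pytest.approx(7.0)
        assert model.evaluate(1e-15) == pytest.approx(7.0)

    def test_matches_brute_force_grid(self):
        model = fs.CylinderTransform(r_nm=1.0, amplitude=1.0)
        x = np.linspace(0.01, 12, 5000)
        np.testing.assert_allclose(
            fs.eval_cylinder_transform(model, x), brute_force_shape_sq(x),
            atol=1e-12,
        )

    def test_first_zero_at_first_j1_null(self):
        model = fs.CylinderTransform(r_nm=1.0)
        x = np.linspace(3.5, 4.2, 70001)
        f2 = model.evaluate(x)
        assert x[np.argmin(f2)] == pytest.approx(3.8317, abs=1e-3)

    def test_subsidiary_maxima_positions(self):
        # dense-grid location of the first two non-zero maxima
        model = fs.CylinderTransform(r_nm=1.0, amplitude=3.0)
        x = np.linspace(0.5, 10, 950001)
        f2 = model.evaluate(x)
        local = np.nonzero((f2[1:-1] > f2[:-2]) & (f2[1:-1] > f2[2:]))[0] + 1
        maxima = x[local[:2]]
        assert round(maxima[0], 2) == 5.14
        assert round(maxima[1], 2) == 8.42
        # positions invariant to amplitude
        f2b = fs.CylinderTransform(r_nm=1.0, amplitude=300.0).evaluate(x)
        localb = np.nonzero((f2b[1:-1] > f2b[:-2]) & (f2b[1:-1] > f2b[2:]))[0] + 1
        np.testing.assert_array_equal(local[:2], localb[:2])

    def test_nonnegative_everywhere(self):
        model = fs.CylinderTransform(r_nm=2.0)
        assert (model.evaluate(np.linspace(0, 50, 10000)) >= 0).all()


class TestFitCylinderTransform:
    def equatorial_profile(self, r_nm=19.1, amp=500.0):
        r = np.arange(20.0, 251.0)
        model = fs.CylinderTransform(r_nm=r_nm, amplitude=amp)
        return RadialProfile(r, model.evaluate(CAL.K(r)), np.ones_like(r, int)), model

    def test_self_consistent_recovery(self):
        prof, model = self.equatorial_profile()
        fit = fs.fit_cylinder_transform(prof, CAL, r_init_nm=17.0, mode="auto")
        assert fit.r_nm == pytest.approx(19.1, rel=0.005)
        assert 2 * fit.r_nm == pytest.approx(38.2, rel=0.005)

    def test_subsidiary_position_inverts_to_radius(self):
        # subsidiary max observed at R_b -> r = 5.1356 / K(R_b)
        prof, _ = self.equatorial_profile(r_nm=15.0)
        r_b = 5.1356223 / (CAL.k_per_pixel * 15.0)
        peak = fs.find_nearest_peak(prof, r_b, window_px=10)
        assert 5.1356223 / CAL.K(peak.position_px) == pytest.approx(15.0, rel=0.01)

    def test_amplitude_scaling_leaves_radius(self):
        prof, _ = self.equatorial_profile()
        scaled = RadialProfile(prof.radius_px, 10 * prof.intensity, prof.n_valid)
        f1 = fs.fit_cylinder_transform(prof, CAL, 17.0, mode="auto")
        f2 = fs.fit_cylinder_transform(scaled, CAL, 17.0, mode="auto")
        assert f2.r_nm == pytest.approx(f1.r_nm, rel=1e-6)
        assert f2.amplitude == pytest.approx(10 * f1.amplitude, rel=1e-6)

    def test_manual_mode_verbatim(self):
        prof, _ = self.equatorial_profile()
        fit = fs.fit_cylinder_transform(prof, CAL, 21.5, amp_init=3.3, mode="manual")
        assert fit.r_nm == 21.5 and fit.amplitude == 3.3


class TestBesselCompensate:
    def make_product_profile(self, r_nm=19.1):
        r = np.arange(20.0, 251.0)
        K = CAL.K(r)
        g0 = 1.0 + 5.0 * np.exp(-((K - 2 * np.pi / 55) ** 2) / (2 * 0.005**2))
        model = fs.CylinderTransform(r_nm=r_nm, amplitude=400.0)
        return RadialProfile(r, g0 * model.evaluate(K), np.ones_like(r, int)), g0, model

    def test_recovers_interference_function(self):
        prof, g0, model = self.make_product_profile()
        g = fs.bessel_compensate(prof, model, CAL)
        defined = np.isfinite(g.intensity)
        assert defined.sum() > 100
        np.testing.assert_allclose(g.intensity[defined], g0[defined], rtol=1e-6)

    def test_profile_equal_to_f2_gives_unity(self):
        r = np.arange(20.0, 251.0)
        model = fs.CylinderTransform(r_nm=19.1, amplitude=2.0)
        prof = RadialProfile(r, model.evaluate(CAL.K(r)), np.ones_like(r, int))
        g = fs.bessel_compensate(prof, model, CAL)
        defined = np.isfinite(g.intensity)
        np.testing.assert_allclose(g.intensity[defined], 1.0, rtol=1e-9)

    def test_bins_near_j1_zero_excluded(self):
        prof, _, model = self.make_product_profile()
        g = fs.bessel_compensate(prof, model, CAL)
        null_px = 3.8317059702 / (CAL.k_per_pixel * 19.1)  # ~128 px
        idx = int(np.argmin(np.abs(g.radius_px - null_px)))
        assert not np.isfinite(g.intensity[idx])
        assert g.n_valid[idx] == 0

    def test_remultiplication_identity(self):
        prof, _, model = self.make_product_profile()
        g = fs.bessel_compensate(prof, model, CAL)
        back = g.intensity * model.evaluate(CAL.K(g.radius_px))
        defined = np.isfinite(back)
        np.testing.assert_allclose(back[defined], prof.intensity[defined], rtol=1e-12)

    def test_all_undefined_raises(self):
        r = np.arange(1.0, 10.0)
        prof = RadialProfile(r, np.full(9, np.nan), np.zeros(9, int))
        with pytest.raises(CompensationError):
            fs.bessel_compensate(prof, fs.CylinderTransform(19.1), CAL)


class TestComputeStructureParams:
    def test_calibrated_arithmetic(self):
        cal = fs.make_calibration(100.0, 67.0)
        mer = fs.PeakMeasurement(300.0, 50.0, 8.0, 296.0, 304.0)
        inter = fs.PeakMeasurement(150.0, 200.0, 10.0, 145.0, 155.0)
        cyl = fs.CylinderTransform(r_nm=19.1, amplitude=1.0)
        params = fs.compute_structure_params(
            cal, meridional=mer, meridional_order=3, interfib=inter, cylinder=cyl
        )
        assert params.d_period_nm == pytest.approx(67.0)
        assert params.bragg_spacing_nm == pytest.approx(67 * 100 / 150)
        assert params.order_param == pytest.approx(20.0)
        assert params.fibril_diameter_nm == pytest.approx(38.2)

    def test_missing_pieces_stay_absent(self):
        params = fs.compute_structure_params(fs.make_calibration(100, 67))
        assert params.d_period_nm is None
        assert params.bragg_spacing_comp_nm is None
        assert params.order_param_comp is None
        assert params.fibril_diameter_nm is None
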