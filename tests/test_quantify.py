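import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from luquant.geometry import VoxelGrid, Cylinder
from luquant.quantify import (
    VOI, make_sphere_voi, make_central_cylinder_voi, make_isocontour_voi,
    voi_counts, calibration_factor, recovery_coefficient, fit_rc_curve,
    eval_rc, quantify, quantification_error, summarize, percent_difference,
    estimate_concentration, CalibrationFactor,
)
from luquant.phantoms import sphere_volume


class FakeRecon:
    """Bare array stand-in carrying only what the VOI math needs."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)


class TestSphereVoi:
    def test_volume_matches_analytic(self, grid64):
        voi = make_sphere_voi(grid64, (0, 0, 0), 50.0)
        assert voi.volume_ml == pytest.approx(sphere_volume(5.0), rel=0.005)
        assert voi.kind == "sphere-physical"

    def test_zero_diameter_rejected(self, grid64):
        with pytest.raises(ValueError):
            make_sphere_voi(grid64, (0, 0, 0), 0.0)

    def test_out_of_grid_rejected(self, grid64):
        with pytest.raises(ValueError):
            make_sphere_voi(grid64, (150.0, 0, 0), 50.0)

    def test_counts_are_weighted_sum(self, grid64):
        voi = make_sphere_voi(grid64, (0, 0, 0), 30.0)
        values = np.full(grid64.shape, 2.0)
        assert voi_counts(FakeRecon(values), voi) == pytest.approx(
            2.0 * voi.weights.sum())


class TestCentralCylinderVoi:
    CYL = Cylinder((0, 0, 0), 105.0, 286.0)

    def test_full_fractions_recover_whole_cylinder(self, grid64):
        voi = make_central_cylinder_voi(grid64, self.CYL, 1.0, 1.0)
        assert voi.volume_ml == pytest.approx(self.CYL.analytic_volume_ml(),
                                              rel=0.01)

    def test_half_fractions_scale_volume(self, grid64):
        """r^2 h scaling: (0.5, 0.5) keeps a quarter of the area and half
        the height."""
        voi = make_central_cylinder_voi(grid64, self.CYL, 0.5, 0.5)
        expected = self.CYL.analytic_volume_ml() * 0.25 * 0.5
        assert voi.volume_ml == pytest.approx(expected, rel=0.01)

    def test_zero_fraction_rejected(self, grid64):
        with pytest.raises(ValueError):
            make_central_cylinder_voi(grid64, self.CYL, 0.0, 0.5)

    def test_too_small_voi_rejected(self, grid64):
        with pytest.raises(ValueError, match="10 voxels"):
            make_central_cylinder_voi(grid64, self.CYL, 0.02, 0.02)


class TestIsocontourVoi:
    def test_binary_object_recovered_exactly(self, grid32):
        img = np.zeros(grid32.shape)
        img[10:20, 10:20, 10:20] = 7.0
        target = 1000 * grid32.voxel_volume_ml
        voi = make_isocontour_voi(img, target,
                                  voxel_volume_ml=grid32.voxel_volume_ml)
        assert voi.volume_ml == pytest.approx(target)
        assert np.array_equal(voi.weights > 0, img > 0)

    def test_blurred_sphere_volume_matched(self, grid32):
        from luquant.geometry import Sphere, fractional_occupancy
        occ = fractional_occupancy(grid32, Sphere((0, 0, 0), 40.0))
        img = ndimage.gaussian_filter(occ, 2.0)
        target = sphere_volume(4.0)
        voi = make_isocontour_voi(img, target,
                                  voxel_volume_ml=grid32.voxel_volume_ml)
        assert abs(voi.volume_ml - target) <= 0.5 * grid32.voxel_volume_ml

    def test_unattainable_target_rejected(self, grid32):
        img = np.zeros(grid32.shape)
        img[0, 0, 0] = 1.0
        with pytest.raises(ValueError, match="unattainable|closest"):
            make_isocontour_voi(img, 1e6,
                                voxel_volume_ml=grid32.voxel_volume_ml)


class TestCalibrationFactor:
    def _uniform_recon_and_voi(self, grid, value):
        voi = make_sphere_voi(grid, (0, 0, 0), 40.0)
        return FakeRecon(np.full(grid.shape, value)), voi

    def test_direct_substitution(self, grid32):
        # CR 100 cps over V=10 ml at TC=1 -> CF = 10
        w = np.zeros(grid32.shape)
        n = int(round(10.0 / grid32.voxel_volume_ml))
        w.flat[:n] = 1.0
        voi = VOI(weights=w, voxel_volume_ml=grid32.voxel_volume_ml, kind="test")
        counts = np.zeros(grid32.shape)
        counts[w > 0] = 100.0 * 60.0 / n  # 100 cps over a 60 s scan
        cf = calibration_factor(FakeRecon(counts), voi, 1.0, 60.0, "cylinder")
        assert cf.value_cps_per_mbq == pytest.approx(
            10.0 * 10.0 / voi.volume_ml, rel=1e-6)

    def test_zero_counts_rejected(self, grid32):
        recon, voi = self._uniform_recon_and_voi(grid32, 0.0)
        with pytest.raises(ValueError):
            calibration_factor(recon, voi, 1.0, 60.0, "sphere")

    def test_printed_cf_pair_difference(self):
        # the two study calibration factors differ by -16.3% of the cylinder
        assert percent_difference(13.9, 16.6, reference="b") == pytest.approx(
            -16.3, abs=0.05)


class TestRecoveryCoefficient:
    def test_identity_and_errors(self):
        assert recovery_coefficient(2.0, 2.0) == 1.0
        with pytest.raises(ValueError):
            recovery_coefficient(1.0, 0.0)

    def test_printed_table_cross_check(self):
        """Cylinder-RC times the CF ratio reproduces the sphere-RC for the
        largest sphere."""
        assert 0.84 * (16.6 / 13.9) == pytest.approx(1.00, abs=0.01)

    def test_cf_rc_reciprocity_is_exact(self, grid32):
        """RC(sphere-CF)/RC(cylinder-CF) = CF_cyl/CF_sph to 1e-12; matched
        CF-RC concentrations are algebraically identical."""
        values = np.abs(np.random.default_rng(5).normal(10, 2, grid32.shape))
        recon = FakeRecon(values)
        voi = make_sphere_voi(grid32, (0, 0, 0), 40.0)
        cf_s = CalibrationFactor(12.4, "sphere")
        cf_c = CalibrationFactor(14.0, "cylinder")
        c_true = 3.04
        rc_s = recovery_coefficient(
            estimate_concentration(recon, voi, cf_s, 1350.0), c_true)
        rc_c = recovery_coefficient(
            estimate_concentration(recon, voi, cf_c, 1350.0), c_true)
        assert rc_s / rc_c == pytest.approx(
            cf_c.value_cps_per_mbq / cf_s.value_cps_per_mbq, abs=1e-12)
        est_s = estimate_concentration(recon, voi, cf_s, 1350.0, rc=rc_s)
        est_c = estimate_concentration(recon, voi, cf_c, 1350.0, rc=rc_c)
        assert est_s == pytest.approx(est_c, rel=1e-12)


class TestRcCurve:
    def test_parameter_recovery_on_noise_free_points(self):
        a, b, c = 1.0, 0.8, 1.2
        x = np.array([1.5, 2.0, 2.5, 3.0, 4.0, 5.0])
        pts = np.column_stack([x, a - b * np.exp(-c * x)])
        curve = fit_rc_curve(pts)
        assert curve.a == pytest.approx(a, abs=1e-6)
        assert curve.b == pytest.approx(b, abs=1e-6)
        assert curve.c == pytest.approx(c, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_flat_points(self):
        pts = np.column_stack([[1.0, 2, 3, 4], np.ones(4)])
        curve = fit_rc_curve(pts)
        assert curve.a == 1.0 and curve.b == 0.0
        assert not curve.c_identifiable

    def test_too_few_or_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            fit_rc_curve([[1.0, 0.5], [2.0, 0.6], [3.0, 0.7]])
        with pytest.raises(ValueError):
            fit_rc_curve([[1.0, 0.5], [1.0, 0.6], [3.0, 0.7], [4.0, 0.8]])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0.5, 1.5), b=st.floats(0.01, 1.0),
           c=st.floats(0.1, 3.0))
    def test_curve_monotone_and_saturating(self, a, b, c):
        from luquant.quantify import RecoveryCurve
        curve = RecoveryCurve(a=a, b=b, c=c, r_squared=1.0,
                              points=np.zeros((0, 2)))
        x = np.linspace(0.1, 30, 200)
        y = eval_rc(curve, x)
        assert np.all(np.diff(y) >= 0)       # flat only once saturated
        assert y[50] > y[0]                  # strictly increasing early on
        assert eval_rc(curve, 1e3) == pytest.approx(a, abs=1e-9)


class TestQuantifyAndSummaries:
    def test_eq2_eq5_consistency(self, grid32):
        """Counts constructed so CR/V = CF*TC quantify with zero error, and
        an RC equal to C_SPECT/C_true zeroes the corrected error exactly."""
        voi = make_sphere_voi(grid32, (0, 0, 0), 40.0)
        cf = CalibrationFactor(14.0, "cylinder")
        tc, t_total = 2.2, 1350.0
        counts = np.zeros(grid32.shape)
        counts[voi.weights > 0] = 1.0
        scale = cf.value_cps_per_mbq * tc * voi.volume_ml * t_total / voi_counts(
            FakeRecon(counts), voi)
        recon = FakeRecon(counts * scale)
        q = quantify(recon, voi, cf, t_total, tc)
        assert q.error_pct == pytest.approx(0.0, abs=1e-9)
        q2 = quantify(recon, voi, cf, t_total, tc * 2)
        rc = q2.c_spect_mbq_ml / (tc * 2) * (1 + 0)  # direct RC
        q3 = quantify(recon, voi, cf, t_total, tc * 2, rc=rc)
        assert q3.error_pct == pytest.approx(0.0, abs=1e-9)

    def test_simple_error_values(self):
        assert quantification_error(1.05, 1.0) == pytest.approx(5.0)
        assert quantification_error(0.95, 1.0) == pytest.approx(-5.0)
        assert quantification_error(3.0, 3.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            quantification_error(1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(c_true=st.floats(0.01, 100), e=st.floats(-0.9, 5.0))
    def test_error_identity(self, c_true, e):
        assert quantification_error(c_true * (1 + e), c_true) == pytest.approx(
            100 * e, rel=1e-9, abs=1e-7)

    def test_summarize_printed_table_columns(self):
        mean, sd = summarize([-4.56, -3.40, -2.05, 1.60])
        assert (round(mean, 2), round(sd, 2)) == (-2.10, 2.67)
        mean, sd = summarize([-20.39, -20.90, -20.32, -18.53], mode="absolute")
        assert (round(mean, 2), round(sd, 2)) == (20.04, 1.04)

    def test_summarize_single_value_sd_undefined(self):
        mean, sd = summarize([3.2])
        assert mean == 3.2 and np.isnan(sd)

    def test_percent_difference_conventions(self):
        assert percent_difference(13.9, 16.6, reference="b") == pytest.approx(-16.27, abs=0.01)
        assert percent_difference(1.18, 0.99, reference="a") == pytest.approx(16.10, abs=0.01)
        assert percent_difference(5.0, 5.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            percent_difference(1.0, 0.0, reference="b")
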