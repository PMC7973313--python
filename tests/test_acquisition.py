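import numpy as np
import pytest

from luquant.geometry import VoxelGrid
from luquant.phantoms import Phantom, build_cylinder_phantom
from luquant.projector import CdrModel
from luquant.acquisition import (
    AcquisitionParams, Orbit, autocontour_orbit, forward_project,
    scatter_component, add_poisson_noise, simulate_acquisition,
    detector_direction,
)
from .conftest import make_point_source, circular_orbit


class TestOrbit:
    def test_validation(self):
        with pytest.raises(ValueError):
            Orbit(np.array([0.0, 120, 240]), np.full(3, 100.0))  # < 4 angles
        with pytest.raises(ValueError):
            Orbit(np.array([0.0, 10, 20, 30]), np.full(4, 100.0))  # not 360

    def test_autocontour_centered_cylinder_is_circular(self, grid32):
        p = build_cylinder_phantom(grid32, radius_mm=55.0, height_mm=110.0,
                                   background_conc=1.0)
        orbit = autocontour_orbit(p.mu, 4.8, 12, margin_mm=20.0)
        # rasterized support can stick out by up to the in-plane half-diagonal
        expected = 55.0 + 20.0 + 2.4
        assert np.all(np.abs(orbit.radii_mm - expected) <= 2.4 + 1e-9)

    def test_autocontour_shifted_object(self, grid64):
        """Brute-force oracle: radius at 0 deg minus radius at 180 deg equals
        twice the shift of the support."""
        mu = grid64.zeros()
        mu[20:50, 28:36, 30:34] = 0.15  # slab offset towards +x
        orbit = autocontour_orbit(mu, 4.8, 8, margin_mm=0.0, min_radius_mm=0.0)
        # oracle: project support extents along each detector direction
        pts = np.argwhere(mu.any(axis=2) > 0) - np.array([31.5, 31.5])
        pts_mm = pts * 4.8
        for ang, radius in zip(orbit.angles_deg, orbit.radii_mm):
            u = detector_direction(ang)
            assert radius == pytest.approx((pts_mm @ u).max() + 2.4, abs=1e-6)
        # the opposing +x / -x views differ by the support's x asymmetry
        i_plus_x = int(np.where(orbit.angles_deg == 270.0)[0][0])
        i_minus_x = int(np.where(orbit.angles_deg == 90.0)[0][0])
        assert (orbit.radii_mm[i_plus_x] - orbit.radii_mm[i_minus_x]
                == pytest.approx(84.0 - 55.2, abs=1e-6))

    def test_autocontour_empty_map_raises(self, grid32):
        with pytest.raises(ValueError, match="empty"):
            autocontour_orbit(grid32.zeros(), 4.8, 12)

    def test_autocontour_single_voxel_zero_margin(self, grid64):
        mu = grid64.zeros()
        mu[32, 32, 32] = 0.15  # +half voxel off centre in x and y
        orbit = autocontour_orbit(mu, 4.8, 4, margin_mm=0.0, min_radius_mm=0.0)
        # radius = voxel-centre projection + half voxel
        for ang, radius in zip(orbit.angles_deg, orbit.radii_mm):
            u = detector_direction(ang)
            assert radius == pytest.approx(np.array([2.4, 2.4]) @ u + 2.4)


class TestForwardProjection:
    def test_zero_activity_projects_to_zero(self, grid32, mini_params):
        p = Phantom(grid=grid32, activity=grid32.zeros(), mu=grid32.zeros(),
                    regions=[])
        proj = forward_project(p, circular_orbit(12, 150.0), mini_params)
        assert proj.counts.sum() == 0

    def test_point_source_count_conservation(self, grid64):
        """In air with CDR off every projection totals A*t*S."""
        params = AcquisitionParams(n_projections=30, matrix=64)
        src = make_point_source(grid64, (36, 30, 32), total_mbq=1.0)
        proj = forward_project(src, circular_orbit(30, 200.0), params,
                               include_cdr=False, include_attenuation=False)
        expected = 1.0 * params.time_per_projection_s * params.sensitivity_cps_per_mbq
        totals = proj.counts.sum(axis=(1, 2))
        assert np.all(np.abs(totals / expected - 1) < 0.005)

    def test_beer_lambert_attenuation(self, grid64):
        """Point source behind ~10 cm of water: ratio of attenuated to
        unattenuated counts follows exp(-mu L)."""
        params = AcquisitionParams(n_projections=4, matrix=64)
        src = make_point_source(grid64, (32, 28, 32))
        mu = grid64.zeros()
        mu[:, 40:61, :] = 0.15          # 21 voxels => 10.08 cm slab
        attenuated = Phantom(grid=grid64, activity=src.activity, mu=mu, regions=[])
        orbit = circular_orbit(4, 200.0)
        p_att = forward_project(attenuated, orbit, params, include_cdr=False)
        p_air = forward_project(src, orbit, params, include_cdr=False,
                                include_attenuation=False)
        ratio = p_att.counts[0].sum() / p_air.counts[0].sum()
        assert ratio == pytest.approx(np.exp(-0.15 * 21 * 0.48), rel=0.01)

    def test_rotational_consistency(self, grid64):
        """A rotationally symmetric phantom projects identically at every
        angle (within interpolation tolerance)."""
        p = build_cylinder_phantom(grid64, background_conc=3.04)
        proj = forward_project(p, circular_orbit(30, 150.0),
                               AcquisitionParams(n_projections=30, matrix=64))
        totals = proj.counts.sum(axis=(1, 2))
        assert (totals.max() - totals.min()) / totals.mean() < 0.01

    def test_cdr_fwhm_monotone_and_calibrated(self, grid64):
        """Fitted projection FWHM of a point source grows with orbit radius
        and matches the 1.1 cm model value at the reference distance."""
        cdr = CdrModel()
        params = AcquisitionParams(n_projections=4, matrix=64, cdr=cdr)
        sigma_src_vox = 1.5
        src = make_point_source(grid64, (32, 32, 32), sigma_vox=sigma_src_vox)
        fitted = []
        radii = [100.0, 150.0, 200.0, 250.0]
        for r in radii:
            proj = forward_project(src, circular_orbit(4, r), params,
                                   include_attenuation=False)
            img = proj.counts[0]
            profile = img.sum(axis=1)
            x = (np.arange(img.shape[0]) - (img.shape[0] - 1) / 2) * 4.8
            mean = (profile * x).sum() / profile.sum()
            var = (profile * (x - mean) ** 2).sum() / profile.sum()
            # remove the known source width to isolate the CDR contribution
            var_cdr = var - (sigma_src_vox * 4.8) ** 2
            fitted.append(2.3548 * np.sqrt(max(var_cdr, 0.0)))
        assert np.all(np.diff(fitted) > 0)
        # source sits half a voxel from the rotation axis
        assert fitted[0] == pytest.approx(cdr.fwhm_mm(100.0 - 2.4), rel=0.05)

    def test_fov_truncation_error(self):
        grid = VoxelGrid((64, 64, 64), 4.8)
        p = build_cylinder_phantom(grid, background_conc=1.0)
        with pytest.raises(Exception, match="field of view"):
            forward_project(p, circular_orbit(4, 200.0),
                            AcquisitionParams(n_projections=4, matrix=32,
                                              pixel_mm=4.8))


class TestScatter:
    def test_scatter_fraction_exact(self, mini_cylinder, mini_params):
        proj = forward_project(mini_cylinder, circular_orbit(12, 150.0),
                               mini_params)
        scat = scatter_component(proj, scatter_fraction=0.2)
        sf = scat.counts.sum() / (proj.counts.sum() + scat.counts.sum())
        assert sf == pytest.approx(0.2, abs=1e-6)

    def test_zero_scatter_cases(self, mini_cylinder, mini_params):
        proj = forward_project(mini_cylinder, circular_orbit(12, 150.0),
                               mini_params)
        assert scatter_component(proj, scatter_fraction=0.0).counts.sum() == 0
        zero = Phantom(grid=mini_cylinder.grid,
                       activity=mini_cylinder.grid.zeros(),
                       mu=mini_cylinder.mu, regions=[])
        pz = forward_project(zero, circular_orbit(12, 150.0), mini_params)
        assert scatter_component(pz, scatter_fraction=0.3).counts.sum() == 0

    def test_invalid_fraction_rejected(self, mini_cylinder, mini_params):
        proj = forward_project(mini_cylinder, circular_orbit(12, 150.0),
                               mini_params)
        with pytest.raises(ValueError):
            scatter_component(proj, scatter_fraction=1.0)


class TestPoissonNoise:
    def test_seed_reproducibility_and_zero_preservation(self, mini_cylinder,
                                                        mini_params):
        proj = forward_project(mini_cylinder, circular_orbit(12, 150.0),
                               mini_params)
        a = add_poisson_noise(proj, seed=7)
        b = add_poisson_noise(proj, seed=7)
        c = add_poisson_noise(proj, seed=8)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)
        assert np.all(a.counts[proj.counts == 0] == 0)

    def test_mean_matches_expectation(self, grid32, mini_params):
        """Law of large numbers on a single hot bin."""
        from luquant.acquisition import ProjectionSet
        expected = np.zeros((12, 32, 32))
        expected[0, 16, 16] = 1e4
        proj = ProjectionSet(counts=expected, orbit=circular_orbit(12, 150.0),
                             params=mini_params)
        draws = [add_poisson_noise(proj, seed=s).counts[0, 16, 16]
                 for s in range(300)]
        assert np.mean(draws) == pytest.approx(1e4, rel=0.01)


def test_simulate_acquisition_components_sum():
    grid = VoxelGrid((32, 32, 32), 4.8)
    p = build_cylinder_phantom(grid, radius_mm=55.0, height_mm=110.0,
                               background_conc=1.0)
    meas, scat_est = simulate_acquisition(
        p, AcquisitionParams(n_projections=12, matrix=32))
    assert np.allclose(meas.counts, meas.primary + meas.scatter)
    assert np.array_equal(scat_est.counts, meas.scatter)
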