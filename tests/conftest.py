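import numpy as np
import pytest
from scipy import ndimage

from luquant.geometry import VoxelGrid
from luquant.phantoms import Phantom, build_cylinder_phantom
from luquant.acquisition import AcquisitionParams, Orbit
from luquant.study import desk_config, run_full_study, run_convergence_study


@pytest.fixture(scope="session")
def grid64():
    return VoxelGrid((64, 64, 64), 4.8)


@pytest.fixture(scope="session")
def grid32():
    return VoxelGrid((32, 32, 32), 4.8)


@pytest.fixture
def mini_params():
    """Small, fast acquisition setup for physics unit tests."""
    return AcquisitionParams(n_projections=12, matrix=32)


def make_point_source(grid, index, total_mbq=1.0, sigma_vox=1.5):
    """Sub-resolution Gaussian blob source (a voxel delta resamples poorly
    under rotation; a narrow blob keeps interpolation error ~0.1%)."""
    act = grid.zeros()
    act[index] = 1.0
    act = ndimage.gaussian_filter(act, sigma_vox)
    act *= total_mbq / (act.sum() * grid.voxel_volume_ml)
    return Phantom(grid=grid, activity=act, mu=grid.zeros(), regions=[])


def circular_orbit(n_angles, radius_mm):
    return Orbit(np.arange(n_angles) * (360.0 / n_angles),
                 np.full(n_angles, float(radius_mm)))


@pytest.fixture(scope="session")
def mini_cylinder(grid32):
    """Small warm cylinder that fits a 32-cube grid."""
    return build_cylinder_phantom(grid32, radius_mm=55.0, height_mm=110.0,
                                  background_conc=1.0)


@pytest.fixture(scope="session")
def desk_report():
    """The full desk-scale study (calibration + RC curves + quantification).

    Session-scoped: this drives every end-to-end assertion, including the
    headline partial-volume-corrected accuracy bound.
    """
    return run_full_study(seed=1)


@pytest.fixture(scope="session")
def convergence_result():
    """Convergence traces for a small and a large sphere plus the kidneys."""
    return run_convergence_study(desk_config(), seed=501,
                                 sphere_volumes_ml=(4.2, 65.4),
                                 ratios=(13.0,), include_kidneys=True)
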