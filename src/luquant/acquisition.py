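"""Analytic SPECT acquisition: orbit, forward projection, scatter, noise.

Stands in for a Monte Carlo camera simulation at desk scale.  Photon
transport is reduced to an attenuated parallel-beam projection with a
distance-dependent Gaussian collimator-detector response; energy-window
physics enters only through a scalar system sensitivity (cps/MBq in the
photopeak) and the attenuation coefficients.  Scatter is modelled as a broad
convolution kernel normalised to a prescribed scatter fraction, applied
identically here and in the reconstruction's forward model (a self-consistent
model-based scatter correction scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy import ndimage

from .phantoms import Phantom
from .projector import CdrModel, SystemModel, FOVError

__all__ = [
    "Orbit", "AcquisitionParams", "ProjectionSet",
    "autocontour_orbit", "forward_project", "scatter_component",
    "add_poisson_noise", "simulate_acquisition",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Orbit:
    """Non-circular camera orbit: one collimator-face radius per angle."""

    angles_deg: np.ndarray
    radii_mm: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=float)
        r = np.asarray(self.radii_mm, dtype=float)
        if a.size < 4:
            raise ValueError("an orbit needs at least 4 angles")
        if a.shape != r.shape:
            raise ValueError("angles and radii must align")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if not np.isclose(a[-1] - a[0], 360.0 * (a.size - 1) / a.size):
            raise ValueError("angles must span 360 degrees equally spaced")
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "radii_mm", r)

    @property
    def n_angles(self) -> int:
        return self.angles_deg.size


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera and protocol parameters.

    The clinical protocol is 60 projections of 45 s on a 128 matrix at
    4.8 mm; `sensitivity_cps_per_mbq` is the effective in-air photopeak
    system sensitivity.
    """

    n_projections: int = 60
    time_per_projection_s: float = 45.0
    matrix: int = 128
    pixel_mm: float = 4.8
    sensitivity_cps_per_mbq: float = 14.0
    cdr: CdrModel = field(default_factory=CdrModel)
    scatter_fraction: float = 0.2
    scatter_kernel_fwhm_mm: float = 80.0
    orbit_margin_mm: float = 20.0
    min_radius_mm: float = 60.0

    def __post_init__(self):
        if self.n_projections < 4:
            raise ValueError("need at least 4 projections")
        if min(self.time_per_projection_s, self.pixel_mm,
               self.sensitivity_cps_per_mbq) <= 0:
            raise ValueError("acquisition parameters must be positive")
        if not 0.0 <= self.scatter_fraction < 1.0:
            raise ValueError("scatter fraction must be in [0, 1)")

    @property
    def total_time_s(self) -> float:
        return self.n_projections * self.time_per_projection_s


@dataclass
class ProjectionSet:
    """Per-angle 2-D count images plus acquisition metadata.

    `counts` has shape (n_angles, nx, nz); expected (real-valued) counts when
    noise-free, integer draws after Poisson noise.  `primary`/`scatter` keep
    the separate noise-free components when available.
    """

    counts: np.ndarray
    orbit: Orbit
    params: AcquisitionParams
    noisy: bool = False
    seed: int | None = None
    primary: np.ndarray | None = None
    scatter: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("projection counts must be non-negative")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def detector_direction(angle_deg: float) -> np.ndarray:
    """Unit vector (x, y) pointing from the rotation axis to the camera."""
    t = np.deg2rad(angle_deg)
    return np.array([-np.sin(t), np.cos(t)])


def autocontour_orbit(mu_map: np.ndarray, voxel_size_mm: float, n_angles: int,
                      margin_mm: float = 20.0, min_radius_mm: float = 60.0) -> Orbit:
    """Orbit following the attenuating support, as an auto-contour would.

    For each angle the radius is the maximal extent of the non-zero density
    support along the viewing direction plus `margin_mm`, floored at
    `min_radius_mm`.
    """
    mu_map = np.asarray(mu_map)
    support = np.argwhere(mu_map.any(axis=2) > 0)
    if support.size == 0:
        raise ValueError("empty density map: no contour to follow")
    nx, ny = mu_map.shape[:2]
    xy_mm = (support - np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])) * voxel_size_mm
    angles = np.arange(n_angles) * (360.0 / n_angles)
    radii = np.empty(n_angles)
    half_voxel = voxel_size_mm / 2.0
    for i, ang in enumerate(angles):
        u = detector_direction(ang)
        extent = float((xy_mm @ u).max()) + half_voxel
        radii[i] = max(extent + margin_mm, min_radius_mm)
    return Orbit(angles_deg=angles, radii_mm=radii)


def _emission_counts_per_projection(phantom: Phantom, params: AcquisitionParams):
    """Per-voxel expected emitted counts during one projection (in air)."""
    return (phantom.activity * phantom.grid.voxel_volume_ml
            * params.sensitivity_cps_per_mbq * params.time_per_projection_s)


def _check_fov(phantom: Phantom, params: AcquisitionParams):
    nx = phantom.grid.shape[0]
    det_extent = params.matrix * params.pixel_mm
    if phantom.grid.shape[0] * phantom.grid.voxel_size_mm > det_extent + 1e-9:
        raise FOVError(
            f"phantom grid ({nx} x {phantom.grid.voxel_size_mm} mm) exceeds the "
            f"detector field of view ({det_extent:.0f} mm); no silent cropping"
        )


def build_system_model(phantom_grid_shape, voxel_size_mm, orbit: Orbit,
                       params: AcquisitionParams, mu=None,
                       include_cdr: bool = True) -> SystemModel:
    return SystemModel(
        shape=phantom_grid_shape,
        voxel_size_mm=voxel_size_mm,
        angles_deg=orbit.angles_deg,
        radii_mm=orbit.radii_mm,
        mu=mu,
        cdr=params.cdr if include_cdr else None,
    )


def forward_project(phantom: Phantom, orbit: Orbit, params: AcquisitionParams,
                    include_cdr: bool = True,
                    include_attenuation: bool = True) -> ProjectionSet:
    """Noise-free primary projections of a phantom.

    Each voxel contributes activity x voxel volume x time x sensitivity,
    attenuated along its ray and spread by the depth-dependent CDR.
    """
    _check_fov(phantom, params)
    model = build_system_model(
        phantom.grid.shape, phantom.grid.voxel_size_mm, orbit, params,
        mu=phantom.mu if include_attenuation else None,
        include_cdr=include_cdr,
    )
    x = _emission_counts_per_projection(phantom, params).astype(np.float32)
    counts = model.project(x).astype(np.float64)
    counts = np.clip(counts, 0.0, None)
    return ProjectionSet(counts=counts, orbit=orbit, params=params,
                         noisy=False, primary=counts.copy(), scatter=None)


def scatter_component(primary: ProjectionSet, scatter_fraction: float | None = None,
                      kernel_fwhm_mm: float | None = None) -> ProjectionSet:
    """Kernel-based scatter estimate scaled to a global scatter fraction.

    The scatter plane per angle is the primary convolved with a broad
    unit-sum Gaussian, rescaled so total scatter / total (primary + scatter)
    equals the scatter fraction exactly on noise-free data.
    """
    if primary.noisy:
        raise ValueError("scatter component must be derived from noise-free primaries")
    params = primary.params
    sf = params.scatter_fraction if scatter_fraction is None else scatter_fraction
    if sf >= 1.0 or sf < 0.0:
        raise ValueError("scatter fraction must be in [0, 1)")
    fwhm = params.scatter_kernel_fwhm_mm if kernel_fwhm_mm is None else kernel_fwhm_mm
    if sf == 0.0 or primary.counts.sum() == 0.0:
        scat = np.zeros_like(primary.counts)
    else:
        sigma_pix = fwhm * _FWHM_TO_SIGMA / params.pixel_mm
        scat = np.stack([
            ndimage.gaussian_filter(p, sigma_pix, mode="constant")
            for p in primary.counts
        ])
        target_total = sf / (1.0 - sf) * primary.counts.sum()
        scat *= target_total / scat.sum()
    return ProjectionSet(counts=scat, orbit=primary.orbit, params=params,
                         noisy=False)


def add_poisson_noise(projections: ProjectionSet, seed: int) -> ProjectionSet:
    """Independent Poisson draw per detector bin; reproducible by seed."""
    if projections.noisy:
        raise ValueError("projections already carry noise")
    if np.any(projections.counts < 0):
        raise ValueError("expected counts must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(projections.counts).astype(np.float64)
    return replace(projections, counts=noisy, noisy=True, seed=seed)


def simulate_acquisition(phantom: Phantom, params: AcquisitionParams,
                         orbit: Orbit | None = None,
                         include_cdr: bool = True,
                         include_attenuation: bool = True,
                         noise_seed: int | None = None):
    """Full acquisition: primary + scatter (+ optional Poisson noise).

    Returns (measured ProjectionSet, scatter estimate ProjectionSet); the
    scatter estimate is the noise-free scatter plane used later as the
    additive term of the reconstruction's forward model.
    """
    if orbit is None:
        orbit = autocontour_orbit(
            phantom.mu, phantom.grid.voxel_size_mm, params.n_projections,
            margin_mm=params.orbit_margin_mm, min_radius_mm=params.min_radius_mm)
    primary = forward_project(phantom, orbit, params,
                              include_cdr=include_cdr,
                              include_attenuation=include_attenuation)
    scatter = scatter_component(primary)
    total = ProjectionSet(counts=primary.counts + scatter.counts,
                          orbit=orbit, params=params, noisy=False,
                          primary=primary.counts, scatter=scatter.counts)
    if noise_seed is not None:
        total = add_poisson_noise(total, noise_seed)
    return total, scatter
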