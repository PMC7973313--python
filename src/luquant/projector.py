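"""Rotation-based parallel-beam system model with attenuation and depth-
dependent collimator-detector response (CDR).

The same operator serves both simulation (forward projection of a phantom's
emission map) and reconstruction (the OS-EM forward/backprojection pair), so
corrections in the reconstruction are modelled exactly as in the acquisition.

Geometry: volumes are (nx, ny, nz) arrays; the camera head views along +y
after the volume is rotated about the z axis; the detector plane bins are
(x, z).  The per-angle attenuation factor exp(-integral of mu dl) is
accumulated along y with a half-voxel offset at the emission voxel.  CDR is a
per-layer 2-D Gaussian whose FWHM grows linearly with the distance between
the layer and the collimator face, FWHM(d) = c0 + c1 * d.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage

__all__ = ["CdrModel", "SystemModel", "rotate_volume", "FOVError"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class FOVError(ValueError):
    """Object support extends beyond the reconstructed/projected field of view."""


@dataclass(frozen=True)
class CdrModel:
    """Linear distance-dependent resolution model.

    Calibrated so FWHM(d_ref) = fwhm_ref; the study default reproduces the
    1.1 cm planar system resolution of a medium-energy collimator at the
    208 keV Lu-177 photopeak, with d_ref = 10 cm (the reference distance is a
    config choice, not a measured quantity).
    """

    fwhm_ref_mm: float = 11.0
    d_ref_mm: float = 100.0
    slope: float = 0.07  # mm FWHM per mm distance

    @property
    def intercept_mm(self) -> float:
        return self.fwhm_ref_mm - self.slope * self.d_ref_mm

    def fwhm_mm(self, distance_mm):
        d = np.maximum(np.asarray(distance_mm, dtype=float), 0.0)
        return self.intercept_mm + self.slope * d


def rotate_volume(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate in the (x, y) plane about the grid centre, linear interpolation.

    Positive angles rotate axis x towards axis y (right-handed about +z).
    Out-of-grid samples are zero.
    """
    if angle_deg % 360.0 == 0.0:
        return vol.copy()
    return ndimage.rotate(
        vol, angle_deg, axes=(1, 0), reshape=False, order=1,
        mode="constant", cval=0.0, prefilter=False,
    )


class SystemModel:
    """Forward/backprojection pair for one acquisition geometry.

    Parameters
    ----------
    voxel_size_mm : float
        Isotropic voxel edge.
    angles_deg, radii_mm : arrays
        Orbit: projection angles and the collimator-face radius per angle.
    mu : array or None
        Attenuation map in cm^-1 (None disables attenuation).
    cdr : CdrModel or None
        None disables the distance-dependent blur.
    """

    def __init__(self, shape, voxel_size_mm, angles_deg, radii_mm,
                 mu=None, cdr: CdrModel | None = None):
        self.shape = tuple(shape)
        self.voxel_size_mm = float(voxel_size_mm)
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.radii_mm = np.asarray(radii_mm, dtype=float)
        if self.radii_mm.shape != self.angles_deg.shape:
            raise ValueError("angles and radii must align")
        self.cdr = cdr
        ny = self.shape[1]
        # y coordinate of each layer (mm, grid-centred); detector sits at +y
        self._y_mm = (np.arange(ny) - (ny - 1) / 2.0) * self.voxel_size_mm
        if np.any(self.radii_mm < 0):
            raise ValueError("orbit radii must be non-negative")
        self._mu = None if mu is None else np.asarray(mu, dtype=np.float32)
        if self._mu is not None and self._mu.shape != self.shape:
            raise ValueError("mu map shape mismatch")
        self._att = self._precompute_attenuation()

    # -- attenuation -------------------------------------------------------
    def _precompute_attenuation(self):
        if self._mu is None:
            return None
        dl_cm = self.voxel_size_mm / 10.0
        att = []
        for ang in self.angles_deg:
            mu_rot = rotate_volume(self._mu, -ang)
            # path from each voxel towards the detector (+y), half-voxel offset
            tail = np.cumsum(mu_rot[:, ::-1, :], axis=1)[:, ::-1, :]
            path = (tail - 0.5 * mu_rot) * dl_cm
            att.append(np.exp(-path, dtype=np.float32))
        return att

    def _sigmas_vox(self, i_angle: int) -> np.ndarray | None:
        if self.cdr is None:
            return None
        d = self.radii_mm[i_angle] - self._y_mm
        return self.cdr.fwhm_mm(d) * _FWHM_TO_SIGMA / self.voxel_size_mm

    # -- single-angle operators -------------------------------------------
    def project_one(self, x: np.ndarray, i_angle: int) -> np.ndarray:
        """Expected detector image (nx, nz) for per-voxel emissions `x`."""
        q = rotate_volume(np.asarray(x, dtype=np.float32), -self.angles_deg[i_angle])
        if self._att is not None:
            q = q * self._att[i_angle]
        sig = self._sigmas_vox(i_angle)
        p = np.zeros((self.shape[0], self.shape[2]), dtype=np.float32)
        for iy in range(self.shape[1]):
            layer = q[:, iy, :]
            if not layer.any():
                continue
            if sig is not None and sig[iy] > 1e-3:
                layer = ndimage.gaussian_filter(layer, sig[iy], mode="constant")
            p += layer
        return p

    def backproject_one(self, r: np.ndarray, i_angle: int) -> np.ndarray:
        """Adjoint of project_one (rotation adjoint approximated by the
        inverse rotation, the standard rotator-projector pairing)."""
        r = np.asarray(r, dtype=np.float32)
        sig = self._sigmas_vox(i_angle)
        b = np.empty(self.shape, dtype=np.float32)
        for iy in range(self.shape[1]):
            if sig is not None and sig[iy] > 1e-3:
                b[:, iy, :] = ndimage.gaussian_filter(r, sig[iy], mode="constant")
            else:
                b[:, iy, :] = r
        if self._att is not None:
            b *= self._att[i_angle]
        return rotate_volume(b, self.angles_deg[i_angle])

    # -- all angles --------------------------------------------------------
    def project(self, x: np.ndarray) -> np.ndarray:
        """Stack of expected projections, shape (n_angles, nx, nz)."""
        return np.stack([self.project_one(x, i) for i in range(len(self.angles_deg))])

    def sensitivity(self, i_angles) -> np.ndarray:
        """Backprojection of unit detector images over the given angles."""
        ones = np.ones((self.shape[0], self.shape[2]), dtype=np.float32)
        s = np.zeros(self.shape, dtype=np.float32)
        for i in i_angles:
            s += self.backproject_one(ones, i)
        return s
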