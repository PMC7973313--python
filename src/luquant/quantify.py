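"""Calibration factors, recovery coefficients and quantification error.

Implements the quantification chain for count-calibrated SPECT volumes:

* CF (cps/MBq) = (CR / V) / TC converts VOI count rates into activity
  concentration, with CR the VOI count rate, V the VOI volume in ml and TC
  the true concentration of the calibration object.
* RC = C_SPECT / C_true measures partial-volume losses for an object; RC as
  a function of sphere diameter x is summarised by the mono-exponential
  curve y = a - b exp(-c x).
* Quantification error (%) = 100 (C_SPECT - C_true) / C_true.

VOIs carry fractional voxel weights; a VOI's counts are the weighted voxel
sum, matching the "mean counts from the fractional voxels" reading used for
all delineations.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage, optimize

from .geometry import VoxelGrid, Sphere, Cylinder, fractional_occupancy
from .recon import ReconVolume

__all__ = [
    "VOI", "CalibrationFactor", "RecoveryCurve", "QuantResult",
    "make_sphere_voi", "make_central_cylinder_voi", "make_isocontour_voi",
    "voi_counts", "calibration_factor", "recovery_coefficient",
    "fit_rc_curve", "eval_rc", "quantify", "quantification_error",
    "summarize", "percent_difference",
]


@dataclass
class VOI:
    """Fractional-weight volume of interest."""

    weights: np.ndarray
    voxel_volume_ml: float
    kind: str  # sphere-physical | central-cylinder | iso-contour

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or np.any(w > 1 + 1e-9):
            raise ValueError("VOI weights must lie in [0, 1]")
        if w.sum() <= 0:
            raise ValueError("VOI is empty")
        self.weights = w

    @property
    def volume_ml(self) -> float:
        return float(self.weights.sum() * self.voxel_volume_ml)


@dataclass(frozen=True)
class CalibrationFactor:
    value_cps_per_mbq: float
    geometry: str            # "sphere" | "cylinder"
    voi_kind: str = ""
    provenance: dict | None = None

    def __post_init__(self):
        if not self.value_cps_per_mbq > 0:
            raise ValueError("calibration factor must be positive")


@dataclass
class RecoveryCurve:
    """Mono-exponential RC model y = a - b exp(-c x), x in cm."""

    a: float
    b: float
    c: float
    r_squared: float
    points: np.ndarray  # (n, 2) diameter_cm, rc
    cf_geometry: str = ""
    c_identifiable: bool = True

    def __call__(self, diameter_cm):
        return eval_rc(self, diameter_cm)


@dataclass(frozen=True)
class QuantResult:
    label: str
    c_spect_mbq_ml: float
    c_true_mbq_ml: float
    cf_geometry: str
    rc_applied: float | None
    error_pct: float


# ---------------------------------------------------------------------------
# VOI construction
# ---------------------------------------------------------------------------

def make_sphere_voi(grid: VoxelGrid, center_mm, diameter_mm: float) -> VOI:
    """Sphere VOI at the object's physical dimensions (fractional weights)."""
    if diameter_mm <= 0:
        raise ValueError("sphere VOI needs a positive diameter")
    shape = Sphere(center_mm=tuple(center_mm), diameter_mm=diameter_mm)
    lo, hi = shape.bounding_box_mm()
    for ax in range(3):
        half = grid.extent_mm[ax] / 2.0
        if lo[ax] < -half or hi[ax] > half:
            raise ValueError("sphere VOI extends outside the grid")
    w = fractional_occupancy(grid, shape)
    voi = VOI(weights=w, voxel_volume_ml=grid.voxel_volume_ml, kind="sphere-physical")
    analytic = shape.analytic_volume_ml()
    if abs(voi.volume_ml - analytic) / analytic > 0.01:
        raise ValueError("sphere VOI volume deviates more than 1% from analytic")
    return voi


def make_central_cylinder_voi(grid: VoxelGrid, cylinder: Cylinder,
                              radial_fraction: float = 0.5,
                              axial_fraction: float = 0.5,
                              min_voxels: int = 10) -> VOI:
    """Coaxial cylindrical VOI in the uniform centre, away from edge effects."""
    if not (0 < radial_fraction <= 1 and 0 < axial_fraction <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    inner = Cylinder(center_mm=cylinder.center_mm,
                     radius_mm=cylinder.radius_mm * radial_fraction,
                     height_mm=cylinder.height_mm * axial_fraction)
    w = fractional_occupancy(grid, inner)
    if (w > 0).sum() < min_voxels:
        raise ValueError("central cylinder VOI smaller than 10 voxels")
    return VOI(weights=w, voxel_volume_ml=grid.voxel_volume_ml,
               kind="central-cylinder")


def make_isocontour_voi(recon, target_volume_ml: float,
                        voxel_volume_ml: float | None = None,
                        restrict_mask: np.ndarray | None = None) -> VOI:
    """Volume-matched iso-contour VOI (binary threshold).

    The count threshold is searched (bisection over the voxel-value axis,
    resolved at the sorted-value level) so that the supra-threshold volume
    matches `target_volume_ml` to within half a voxel.  All supra-threshold
    voxels are kept; `restrict_mask` optionally limits the search to a
    neighbourhood, e.g. one kidney's surroundings.
    """
    if isinstance(recon, ReconVolume):
        values = recon.values
        vv = (recon.voxel_size_mm / 10.0) ** 3
    else:
        values = np.asarray(recon, dtype=float)
        if voxel_volume_ml is None:
            raise ValueError("voxel_volume_ml required for a bare array")
        vv = voxel_volume_ml
    if values.max() <= 0:
        raise ValueError("image has no positive voxels to contour")
    mask = np.ones(values.shape, bool) if restrict_mask is None else np.asarray(restrict_mask, bool)
    candidates = values[mask]
    achievable = candidates[candidates > 0].size * vv
    k = int(round(target_volume_ml / vv))
    if k < 1 or target_volume_ml > achievable + 0.5 * vv:
        raise ValueError(
            f"target volume {target_volume_ml:.1f} ml unattainable; closest "
            f"achievable {min(achievable, max(vv, 0.0)):.1f}..{achievable:.1f} ml")
    # descending value order; the k-th largest value is the threshold
    order = np.argsort(candidates)[::-1]
    threshold = candidates[order[k - 1]]
    w = np.zeros(values.shape)
    sel = mask & (values >= threshold)
    # ties at the threshold could overshoot; trim surplus tied voxels
    surplus = int(sel.sum()) - k
    if surplus > 0:
        tied = np.argwhere(sel & (values == threshold))
        for idx in tied[:surplus]:
            sel[tuple(idx)] = False
    w[sel] = 1.0
    voi = VOI(weights=w, voxel_volume_ml=vv, kind="iso-contour")
    if abs(voi.volume_ml - target_volume_ml) > 0.5 * vv + 1e-9:
        raise ValueError("iso-contour volume missed the target by over half a voxel")
    return voi


def voi_counts(recon, voi: VOI) -> float:
    """Total counts attributable to a VOI: weighted voxel sum."""
    values = np.asarray(getattr(recon, "values", recon))
    return float((values * voi.weights).sum())


# ---------------------------------------------------------------------------
# calibration and recovery
# ---------------------------------------------------------------------------

def calibration_factor(recon, voi: VOI, true_conc_mbq_ml: float,
                       acq_time_total_s: float, geometry: str,
                       provenance: dict | None = None) -> CalibrationFactor:
    """CF (cps/MBq) = (CR / V) / TC with CR = VOI counts / total scan time."""
    if true_conc_mbq_ml <= 0:
        raise ValueError("true concentration must be positive")
    counts = voi_counts(recon, voi)
    if counts <= 0:
        raise ValueError("VOI contains no counts")
    cr = counts / acq_time_total_s
    cf = (cr / voi.volume_ml) / true_conc_mbq_ml
    return CalibrationFactor(value_cps_per_mbq=cf, geometry=geometry,
                             voi_kind=voi.kind, provenance=provenance)


def recovery_coefficient(c_spect: float, c_true: float) -> float:
    """RC = C_SPECT / C_true (unclamped; spill-in can push it above 1)."""
    if c_true <= 0:
        raise ValueError("true concentration must be positive")
    return c_spect / c_true


def fit_rc_curve(points, cf_geometry: str = "") -> RecoveryCurve:
    """Least-squares fit of y = a - b exp(-c x) to (diameter_cm, RC) points.

    Constraints b >= 0, c > 0 keep the curve monotone increasing.  If all RC
    values coincide the curve degenerates to a = y, b = 0 with a flagged
    non-identifiable rate constant.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (diameter, RC) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size != x.size:
        raise ValueError("diameters must be distinct")

    if np.allclose(y, y[0]):
        return RecoveryCurve(a=float(y[0]), b=0.0, c=1.0, r_squared=1.0,
                             points=pts, cf_geometry=cf_geometry,
                             c_identifiable=False)

    def model(x, a, b, c):
        return a - b * np.exp(-c * x)

    a0 = float(y.max())
    b0 = max(float(y.max() - y.min()), 1e-3)
    c0 = 1.0 / max(float(x.mean()), 1e-6)
    (a, b, c), _ = optimize.curve_fit(
        model, x, y, p0=(a0, b0, c0),
        bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = y - model(x, a, b, c)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean())**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RecoveryCurve(a=float(a), b=float(b), c=float(c),
                         r_squared=max(min(r2, 1.0), 0.0),
                         points=pts, cf_geometry=cf_geometry)


def eval_rc(curve: RecoveryCurve, diameter_cm):
    return curve.a - curve.b * np.exp(-curve.c * np.asarray(diameter_cm, dtype=float))


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def estimate_concentration(recon, voi: VOI, cf: CalibrationFactor,
                           acq_time_total_s: float,
                           rc: float | None = None) -> float:
    """SPECT-estimated concentration (MBq/ml), optionally partial-volume
    corrected by dividing by a recovery coefficient."""
    if rc is not None and rc <= 0:
        raise ValueError("recovery coefficient must be positive")
    cr = voi_counts(recon, voi) / acq_time_total_s
    c = (cr / voi.volume_ml) / cf.value_cps_per_mbq
    if rc is not None:
        c = c / rc
    return c


def quantification_error(c_spect: float, c_true: float) -> float:
    """Percent difference of the estimate from the truth."""
    if c_true == 0:
        raise ZeroDivisionError("true concentration is zero")
    return 100.0 * (c_spect - c_true) / c_true


def quantify(recon, voi: VOI, cf: CalibrationFactor, acq_time_total_s: float,
             c_true: float, rc: float | None = None,
             label: str = "") -> QuantResult:
    if c_true <= 0:
        raise ValueError("ground-truth concentration required (must be > 0)")
    c_spect = estimate_concentration(recon, voi, cf, acq_time_total_s, rc=rc)
    return QuantResult(
        label=label,
        c_spect_mbq_ml=c_spect,
        c_true_mbq_ml=c_true,
        cf_geometry=cf.geometry,
        rc_applied=rc,
        error_pct=quantification_error(c_spect, c_true),
    )


def summarize(errors, mode: str = "signed") -> tuple[float, float]:
    """Mean and sample SD (n-1) of quantification errors.

    mode="absolute" summarises |errors| (the "absolute average" convention);
    the SD is undefined (NaN) for a single value rather than zero.
    """
    e = np.asarray(list(errors), dtype=float)
    if e.size < 1:
        raise ValueError("need at least one error value")
    if mode == "absolute":
        e = np.abs(e)
    elif mode != "signed":
        raise ValueError("mode must be 'signed' or 'absolute'")
    mean = float(e.mean())
    sd = float(e.std(ddof=1)) if e.size > 1 else float("nan")
    return mean, sd


def percent_difference(a: float, b: float, reference: str = "b") -> float:
    """100 (a - b) / reference, reference being 'a' or 'b'."""
    ref = a if reference == "a" else b
    if ref == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (a - b) / ref
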