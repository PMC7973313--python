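"""Voxelized activity/attenuation phantoms with region ground truth.

The generators emulate the three study geometries: a 9900 ml water cylinder,
a torso-like compartment phantom (lungs / liver / body shell) and a
patient-like phantom (liver, lungs, spleen, two kidneys inside a large body
compartment), each with configurable sphere inserts.  Every region's realized
(rasterized) volume is tracked and must land within 1% of its analytic target.

Linear attenuation defaults are physical estimates for the 208 keV Lu-177
photopeak: water-equivalent soft tissue 0.136 cm^-1 and inflated lung
(density ~0.3 g/ml) 0.041 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .geometry import (
    VoxelGrid,
    Shape,
    Sphere,
    Cylinder,
    Ellipsoid,
    EllipticCylinder,
    fractional_occupancy,
)

__all__ = [
    "MU_WATER_CM", "MU_LUNG_CM", "MU_AIR_CM",
    "Region", "Phantom", "OrganSpec", "CompartmentSpec",
    "sphere_volume", "build_cylinder_phantom", "add_sphere",
    "build_compartment_phantom", "build_patient_like_phantom",
    "build_torso_phantom", "torso_spec", "patient_spec",
    "GeometryError", "OverlapError",
]

MU_WATER_CM = 0.136
MU_LUNG_CM = 0.041
MU_AIR_CM = 0.0

VOLUME_TOL = 0.01  # realized region volume must match target to 1%


class GeometryError(ValueError):
    """Shape does not fit the grid / host region."""


class OverlapError(ValueError):
    """Two inserts would occupy the same voxels."""


@dataclass
class Region:
    """One labelled compartment of a phantom.

    `occupancy` holds the fractional voxel weights the region was rasterized
    with; `realized_volume_ml` is their sum times the voxel volume.
    """

    label: str
    shape: Shape
    concentration_mbq_ml: float
    mu_cm: float
    target_volume_ml: float | None = None
    realized_volume_ml: float = 0.0
    occupancy: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.concentration_mbq_ml < 0:
            raise ValueError("concentration must be non-negative")
        if self.mu_cm < 0:
            raise ValueError("attenuation coefficient must be non-negative")


@dataclass
class Phantom:
    grid: VoxelGrid
    activity: np.ndarray  # MBq/ml per voxel
    mu: np.ndarray        # cm^-1 per voxel
    regions: list[Region] = field(default_factory=list)

    @property
    def total_activity_mbq(self) -> float:
        return float(self.activity.sum() * self.grid.voxel_volume_ml)

    def region(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)

    def copy(self) -> "Phantom":
        return Phantom(
            grid=self.grid,
            activity=self.activity.copy(),
            mu=self.mu.copy(),
            regions=[replace(r, occupancy=None if r.occupancy is None else r.occupancy.copy())
                     for r in self.regions],
        )


def sphere_volume(diameter_cm: float) -> float:
    """Volume in ml of a sphere of the given diameter in cm."""
    if diameter_cm < 0:
        raise ValueError("diameter must be non-negative")
    return (4.0 / 3.0) * np.pi * (diameter_cm / 2.0) ** 3


def _check_fits(grid: VoxelGrid, shape: Shape, margin_voxels: float = 2.0):
    lo, hi = shape.bounding_box_mm()
    margin = margin_voxels * grid.voxel_size_mm
    names = "xyz"
    for ax in range(3):
        half = grid.extent_mm[ax] / 2.0
        if lo[ax] < -half + margin or hi[ax] > half - margin:
            raise GeometryError(
                f"shape exceeds grid along {names[ax]}-axis: extent "
                f"[{lo[ax]:.1f}, {hi[ax]:.1f}] mm vs grid half-extent "
                f"{half:.1f} mm (margin {margin:.1f} mm)"
            )


def _rasterize(grid, shape, target_volume_ml=None, supersample=None) -> np.ndarray:
    occ = fractional_occupancy(grid, shape, supersample=supersample)
    realized = occ.sum() * grid.voxel_volume_ml
    target = target_volume_ml if target_volume_ml is not None else shape.analytic_volume_ml()
    if target > 0 and abs(realized - target) / target > VOLUME_TOL:
        raise GeometryError(
            f"rasterized volume {realized:.2f} ml deviates more than 1% from "
            f"target {target:.2f} ml"
        )
    return occ


def _scale_free_axis(shape: Shape, factor: float) -> Shape:
    """Rescale a shape so its volume changes by `factor`.

    Cylinders are scaled through their curved cross-section (the flat end
    faces respond to supersampling in coarse quanta, the lateral surface
    quasi-continuously); ellipsoids through their z semi-axis.
    """
    if isinstance(shape, EllipticCylinder):
        a, b = shape.semi_axes_xy_mm
        s = float(np.sqrt(factor))
        return replace(shape, semi_axes_xy_mm=(a * s, b * s))
    if isinstance(shape, Cylinder):
        return replace(shape, radius_mm=shape.radius_mm * float(np.sqrt(factor)))
    if isinstance(shape, Ellipsoid):
        a, b, c = shape.semi_axes_mm
        return replace(shape, semi_axes_mm=(a, b, c * factor))
    raise TypeError(f"cannot volume-match a {type(shape).__name__}")


def _rasterize_volume_matched(grid, shape, target_volume_ml, supersample=None,
                              max_iter=4):
    """Rasterize, nudging the shape's free axis so the realized volume hits
    the target to ~0.1%.  Returns (occupancy, adjusted shape)."""
    occ = fractional_occupancy(grid, shape, supersample=supersample)
    for _ in range(max_iter):
        realized = occ.sum() * grid.voxel_volume_ml
        if realized <= 0 or abs(realized - target_volume_ml) / target_volume_ml < 1e-3:
            break
        shape = _scale_free_axis(shape, target_volume_ml / realized)
        occ = fractional_occupancy(grid, shape, supersample=supersample)
    realized = occ.sum() * grid.voxel_volume_ml
    if abs(realized - target_volume_ml) / target_volume_ml > VOLUME_TOL:
        raise GeometryError(
            f"volume matching failed: realized {realized:.2f} ml vs target "
            f"{target_volume_ml:.2f} ml"
        )
    return occ, shape


def build_cylinder_phantom(
    grid: VoxelGrid,
    radius_mm: float = 105.0,
    height_mm: float = 286.0,
    background_conc: float = 0.0,
    mu_medium: float = MU_WATER_CM,
    supersample: int | None = None,
) -> Phantom:
    """Water cylinder phantom (defaults realize the 9900 ml study cylinder)."""
    shape = Cylinder(center_mm=(0.0, 0.0, 0.0), radius_mm=radius_mm, height_mm=height_mm)
    _check_fits(grid, shape)
    occ = _rasterize(grid, shape, supersample=supersample)
    region = Region(
        label="cylinder",
        shape=shape,
        concentration_mbq_ml=background_conc,
        mu_cm=mu_medium,
        target_volume_ml=shape.analytic_volume_ml(),
        realized_volume_ml=float(occ.sum() * grid.voxel_volume_ml),
        occupancy=occ,
    )
    return Phantom(
        grid=grid,
        activity=background_conc * occ,
        mu=mu_medium * occ,
        regions=[region],
    )


def add_sphere(
    phantom: Phantom,
    center_mm: tuple[float, float, float],
    diameter_mm: float,
    conc_mbq_ml: float,
    label: str | None = None,
    mu_cm: float | None = None,
    supersample: int | None = None,
) -> Phantom:
    """Insert a uniform sphere, mixing boundary voxels by fractional occupancy.

    The sphere must lie entirely inside an existing (host) region and must not
    touch a previously added insert.  Returns a new phantom; the input is not
    modified.
    """
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    if diameter_mm == 0:
        return phantom.copy()

    grid = phantom.grid
    shape = Sphere(center_mm=center_mm, diameter_mm=diameter_mm)
    _check_fits(grid, shape, margin_voxels=0.0)
    occ = _rasterize(grid, shape, supersample=supersample)

    support = occ > 0
    # The first region is the host compartment; everything after it (organs,
    # previously added spheres) is an insert the new sphere must not touch.
    if not phantom.regions or phantom.regions[0].occupancy is None:
        raise GeometryError("phantom has no host region to place the sphere in")
    host_occ = phantom.regions[0].occupancy
    if np.any(host_occ[support] < occ[support] - 1e-9):
        raise GeometryError("sphere is not entirely inside the host region")
    for r in phantom.regions[1:]:
        if r.occupancy is not None and float((r.occupancy * occ).sum()) > 1e-9:
            raise OverlapError(f"sphere overlaps existing insert '{r.label}'")

    new = phantom.copy()
    new.activity = new.activity * (1.0 - occ) + conc_mbq_ml * occ
    if mu_cm is not None:
        new.mu = new.mu * (1.0 - occ) + mu_cm * occ
    name = label or f"sphere:{diameter_mm:g}mm"
    new.regions.append(
        Region(
            label=name if name.startswith("sphere:") else f"sphere:{name}",
            shape=shape,
            concentration_mbq_ml=conc_mbq_ml,
            mu_cm=mu_cm if mu_cm is not None else float("nan"),
            target_volume_ml=shape.analytic_volume_ml(),
            realized_volume_ml=float(occ.sum() * grid.voxel_volume_ml),
            occupancy=occ,
        )
    )
    return new


# ---------------------------------------------------------------------------
# Compartment phantoms (torso-like, patient-like)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganSpec:
    label: str
    shape: Shape
    concentration_mbq_ml: float
    mu_cm: float = MU_WATER_CM
    target_volume_ml: float | None = None


@dataclass(frozen=True)
class CompartmentSpec:
    body: OrganSpec
    organs: tuple[OrganSpec, ...] = ()
    # attenuating-only surround (e.g. the bulk of a physical torso phantom
    # outside its activity-fillable compartments); no activity
    shell: OrganSpec | None = None


def build_compartment_phantom(
    grid: VoxelGrid, spec: CompartmentSpec, supersample: int | None = None
) -> Phantom:
    """Body compartment with non-overlapping organ inserts.

    Organs override the body background by fractional occupancy; organs
    overlapping each other raise OverlapError.  The body OrganSpec's target is
    the *remainder* volume (body net of organs); the gross body solid is
    volume-matched to remainder + sum of organ targets, so both the organs and
    the remainder land on their segmentation truth values.
    """
    body = spec.body
    _check_fits(grid, body.shape, margin_voxels=1.5)
    organ_total = sum(o.target_volume_ml or o.shape.analytic_volume_ml()
                      for o in spec.organs)
    remainder_target = (body.target_volume_ml
                        if body.target_volume_ml is not None
                        else body.shape.analytic_volume_ml() - organ_total)
    gross_target = remainder_target + organ_total
    body_occ, body_shape = _rasterize_volume_matched(
        grid, body.shape, gross_target, supersample=supersample)

    activity = body.concentration_mbq_ml * body_occ
    mu = body.mu_cm * body_occ
    occupied = np.zeros(grid.shape)
    regions = []

    for organ in spec.organs:
        target = organ.target_volume_ml or organ.shape.analytic_volume_ml()
        occ, oshape = _rasterize_volume_matched(grid, organ.shape, target,
                                                supersample=supersample)
        if float((occupied * occ).sum()) > 1e-9:
            raise OverlapError(f"organ '{organ.label}' overlaps a previous organ")
        occupied += occ
        activity = activity * (1.0 - occ) + organ.concentration_mbq_ml * occ
        mu = mu * (1.0 - occ) + organ.mu_cm * occ
        regions.append(
            Region(
                label=organ.label,
                shape=oshape,
                concentration_mbq_ml=organ.concentration_mbq_ml,
                mu_cm=organ.mu_cm,
                target_volume_ml=target,
                realized_volume_ml=float(occ.sum() * grid.voxel_volume_ml),
                occupancy=occ,
            )
        )

    shell_region = None
    if spec.shell is not None:
        _check_fits(grid, spec.shell.shape, margin_voxels=1.5)
        outer = fractional_occupancy(grid, spec.shell.shape)
        shell_occ = np.clip(outer - body_occ, 0.0, 1.0)
        mu = mu + spec.shell.mu_cm * shell_occ
        shell_region = Region(
            label=spec.shell.label,
            shape=spec.shell.shape,
            concentration_mbq_ml=0.0,
            mu_cm=spec.shell.mu_cm,
            target_volume_ml=float(shell_occ.sum() * grid.voxel_volume_ml),
            realized_volume_ml=float(shell_occ.sum() * grid.voxel_volume_ml),
            occupancy=shell_occ,
        )

    body_net = np.clip(body_occ - occupied, 0.0, 1.0)
    body_region = Region(
        label=body.label,
        shape=body_shape,
        concentration_mbq_ml=body.concentration_mbq_ml,
        mu_cm=body.mu_cm,
        target_volume_ml=remainder_target,
        realized_volume_ml=float(body_net.sum() * grid.voxel_volume_ml),
        occupancy=body_occ,
    )
    all_regions = [body_region] + regions
    if shell_region is not None:
        all_regions.append(shell_region)
    return Phantom(grid=grid, activity=activity, mu=mu, regions=all_regions)


def _ellipsoid_for_volume(center, a_mm, b_mm, volume_ml) -> Ellipsoid:
    """Ellipsoid with two fixed semi-axes, the third solved from the volume."""
    c_cm = volume_ml / ((4.0 / 3.0) * np.pi * (a_mm / 10.0) * (b_mm / 10.0))
    return Ellipsoid(center_mm=center, semi_axes_mm=(a_mm, b_mm, c_cm * 10.0))


def _elliptic_cylinder_for_volume(center, a_mm, b_mm, volume_ml) -> EllipticCylinder:
    h_cm = volume_ml / (np.pi * (a_mm / 10.0) * (b_mm / 10.0))
    return EllipticCylinder(center_mm=center, semi_axes_xy_mm=(a_mm, b_mm),
                            height_mm=h_cm * 10.0)


def torso_spec(
    lung_conc: float = 0.34,
    liver_conc: float = 0.51,
    background_conc: float = 0.17,
) -> CompartmentSpec:
    """Torso-like compartment phantom.

    Volumes mirror the segmented RSD torso: lungs 2×1045 ml, liver 1090 ml and
    a 2095 ml soft-tissue remainder (activity-fillable body 5275 ml gross).
    Lungs are elliptic cylinders stacked above the liver slab so nothing
    overlaps on a 64-cube desk grid.  A water-equivalent attenuating-only
    shell surrounds the compartments, bringing the attenuating cross-section
    to human-torso scale — physical torso phantoms are large attenuating
    objects of which only the fillable compartments carry activity.
    """
    body = OrganSpec(
        label="body",
        shape=_elliptic_cylinder_for_volume((0.0, 0.0, 0.0), 100.0, 70.0, 5275.0),
        concentration_mbq_ml=background_conc,
        mu_cm=MU_WATER_CM,
        target_volume_ml=2095.0,  # remainder (soft-tissue shell)
    )
    lungs = tuple(
        OrganSpec(
            label=lab,
            shape=_elliptic_cylinder_for_volume((sx, 0.0, 55.0), 45.0, 60.0, 1045.0),
            concentration_mbq_ml=lung_conc,
            mu_cm=MU_LUNG_CM,
            target_volume_ml=1045.0,
        )
        for lab, sx in (("lung_left", -47.0), ("lung_right", 47.0))
    )
    liver = OrganSpec(
        label="liver",
        shape=EllipticCylinder(center_mm=(38.0, 0.0, -64.0),
                               semi_axes_xy_mm=(58.0, 57.0), height_mm=105.0),
        concentration_mbq_ml=liver_conc,
        mu_cm=MU_WATER_CM,
        target_volume_ml=1090.0,
    )
    shell = OrganSpec(
        label="shell",
        shape=EllipticCylinder(center_mm=(0.0, 0.0, 0.0),
                               semi_axes_xy_mm=(140.0, 95.0), height_mm=260.0),
        concentration_mbq_ml=0.0,
        mu_cm=MU_WATER_CM,
    )
    return CompartmentSpec(body=body, organs=lungs + (liver,), shell=shell)


def patient_spec(
    liver_conc: float = 0.51,
    lung_conc: float = 0.34,
    spleen_conc: float = 0.52,
    kidney_conc: float = 0.45,
    background_conc: float = 0.02,
) -> CompartmentSpec:
    """Patient-like compartment phantom with the study's organ volumes.

    liver 1590 ml, lungs 2×1135 ml, spleen 160 ml, left/right kidneys
    159/169 ml, body 14,100 ml.  Default concentrations reflect a 24 h
    Lu-177-DOTATATE distribution (kidney:background 0.45/0.02 ~ 23:1).
    """
    # remaining-patient volume is 14,100 ml *net* of organs -> gross ~18,450 ml
    gross_ml = 14100.0 + 2 * 1135.0 + 1590.0 + 160.0 + 159.0 + 169.0
    body = OrganSpec(
        label="body",
        shape=_elliptic_cylinder_for_volume((0.0, 0.0, 0.0), 145.0, 141.0, gross_ml),
        concentration_mbq_ml=background_conc,
        mu_cm=MU_WATER_CM,
        target_volume_ml=14100.0,  # remainder
    )
    lungs = tuple(
        OrganSpec(
            label=lab,
            shape=_ellipsoid_for_volume((sx, 0.0, 78.0), 64.0, 70.0, 1135.0),
            concentration_mbq_ml=lung_conc,
            mu_cm=MU_LUNG_CM,
            target_volume_ml=1135.0,
        )
        for lab, sx in (("lung_left", -68.0), ("lung_right", 68.0))
    )
    liver = OrganSpec(
        label="liver",
        shape=_ellipsoid_for_volume((50.0, 25.0, -58.0), 80.0, 65.0, 1590.0),
        concentration_mbq_ml=liver_conc,
        target_volume_ml=1590.0,
    )
    spleen = OrganSpec(
        label="spleen",
        shape=_ellipsoid_for_volume((-90.0, 35.0, -30.0), 34.0, 32.0, 160.0),
        concentration_mbq_ml=spleen_conc,
        target_volume_ml=160.0,
    )
    kidneys = tuple(
        OrganSpec(
            label=lab,
            shape=_ellipsoid_for_volume((sx, -72.0, -75.0), 28.0, 27.0, vol),
            concentration_mbq_ml=kidney_conc,
            target_volume_ml=vol,
        )
        for lab, sx, vol in (("kidney_left", -58.0, 159.0),
                             ("kidney_right", 58.0, 169.0))
    )
    return CompartmentSpec(body=body, organs=lungs + (liver, spleen) + kidneys)


def build_patient_like_phantom(grid: VoxelGrid, spec: CompartmentSpec | None = None,
                               supersample: int | None = None) -> Phantom:
    return build_compartment_phantom(grid, spec or patient_spec(), supersample=supersample)


def build_torso_phantom(grid: VoxelGrid, spec: CompartmentSpec | None = None,
                        supersample: int | None = None) -> Phantom:
    return build_compartment_phantom(grid, spec or torso_spec(), supersample=supersample)
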