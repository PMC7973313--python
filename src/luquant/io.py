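"""NIfTI + JSON-sidecar persistence for phantoms, projections and recons.

Volumes go to .nii.gz with a diagonal affine (voxel size on the diagonal,
grid-centred origin); everything that is not a voxel array — region truth
tables, orbit radii, acquisition parameters, seeds, reconstruction
provenance — goes to a JSON sidecar next to the image.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import VoxelGrid
from .phantoms import Phantom, Region
from .projector import CdrModel
from .acquisition import Orbit, AcquisitionParams, ProjectionSet
from .recon import ReconParams, ReconVolume

__all__ = [
    "save_phantom", "load_phantom",
    "save_projections", "load_projections",
    "save_recon", "load_recon",
]


def _affine(voxel_size_mm: float, shape) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size_mm
    return aff


def _save_nifti(path, data, voxel_size_mm):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size_mm, data.shape[:3]))
    nib.save(img, str(path))


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_phantom(phantom: Phantom, activity_path, mu_path=None) -> None:
    """Write activity (and optionally mu) volumes plus the region truth table."""
    activity_path = Path(activity_path)
    vs = phantom.grid.voxel_size_mm
    _save_nifti(activity_path, phantom.activity, vs)
    if mu_path is not None:
        _save_nifti(mu_path, phantom.mu, vs)
    meta = {
        "voxel_size_mm": vs,
        "shape": list(phantom.grid.shape),
        "total_activity_mbq": phantom.total_activity_mbq,
        "regions": [
            {
                "label": r.label,
                "concentration_mbq_ml": r.concentration_mbq_ml,
                "mu_cm": None if np.isnan(r.mu_cm) else r.mu_cm,
                "target_volume_ml": r.target_volume_ml,
                "realized_volume_ml": r.realized_volume_ml,
            }
            for r in phantom.regions
        ],
    }
    _sidecar(activity_path).write_text(json.dumps(meta, indent=1))


def load_phantom(activity_path, mu_path=None) -> Phantom:
    """Reload a phantom written by save_phantom.

    Region occupancy maps are not persisted; the returned regions carry the
    truth-table scalars only.
    """
    activity_path = Path(activity_path)
    img = nib.load(str(activity_path))
    activity = np.asarray(img.dataobj, dtype=np.float64)
    meta = json.loads(_sidecar(activity_path).read_text())
    grid = VoxelGrid(tuple(meta["shape"]), meta["voxel_size_mm"])
    mu = (np.asarray(nib.load(str(mu_path)).dataobj, dtype=np.float64)
          if mu_path is not None else grid.zeros())
    regions = [
        Region(label=r["label"], shape=None,
               concentration_mbq_ml=r["concentration_mbq_ml"],
               mu_cm=r["mu_cm"] if r["mu_cm"] is not None else 0.0,
               target_volume_ml=r["target_volume_ml"],
               realized_volume_ml=r["realized_volume_ml"])
        for r in meta["regions"]
    ]
    return Phantom(grid=grid, activity=activity, mu=mu, regions=regions)


def save_projections(proj: ProjectionSet, path) -> None:
    path = Path(path)
    # angle axis last so the stack views as a 3-D image
    _save_nifti(path, np.moveaxis(proj.counts, 0, -1), proj.params.pixel_mm)
    p = proj.params
    meta = {
        "angles_deg": proj.orbit.angles_deg.tolist(),
        "radii_mm": proj.orbit.radii_mm.tolist(),
        "noisy": proj.noisy,
        "seed": proj.seed,
        "params": {
            "n_projections": p.n_projections,
            "time_per_projection_s": p.time_per_projection_s,
            "matrix": p.matrix,
            "pixel_mm": p.pixel_mm,
            "sensitivity_cps_per_mbq": p.sensitivity_cps_per_mbq,
            "cdr": dataclasses.asdict(p.cdr),
            "scatter_fraction": p.scatter_fraction,
            "scatter_kernel_fwhm_mm": p.scatter_kernel_fwhm_mm,
            "orbit_margin_mm": p.orbit_margin_mm,
            "min_radius_mm": p.min_radius_mm,
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_projections(path) -> ProjectionSet:
    path = Path(path)
    counts = np.moveaxis(np.asarray(nib.load(str(path)).dataobj, dtype=np.float64),
                         -1, 0)
    meta = json.loads(_sidecar(path).read_text())
    pm = meta["params"]
    params = AcquisitionParams(
        n_projections=pm["n_projections"],
        time_per_projection_s=pm["time_per_projection_s"],
        matrix=pm["matrix"],
        pixel_mm=pm["pixel_mm"],
        sensitivity_cps_per_mbq=pm["sensitivity_cps_per_mbq"],
        cdr=CdrModel(**pm["cdr"]),
        scatter_fraction=pm["scatter_fraction"],
        scatter_kernel_fwhm_mm=pm["scatter_kernel_fwhm_mm"],
        orbit_margin_mm=pm["orbit_margin_mm"],
        min_radius_mm=pm["min_radius_mm"],
    )
    orbit = Orbit(np.asarray(meta["angles_deg"]), np.asarray(meta["radii_mm"]))
    return ProjectionSet(counts=counts, orbit=orbit, params=params,
                         noisy=meta["noisy"], seed=meta["seed"])


def save_recon(recon: ReconVolume, path) -> None:
    path = Path(path)
    _save_nifti(path, recon.values, recon.voxel_size_mm)
    rp = recon.params
    meta = {
        "voxel_size_mm": recon.voxel_size_mm,
        "acq_time_total_s": recon.acq_time_total_s,
        "params": {
            "n_subsets": rp.n_subsets,
            "n_iterations": rp.n_iterations,
            "updates": rp.updates,
            "attenuation": rp.attenuation,
            "scatter": rp.scatter,
            "cdr": rp.cdr,
            "checkpoints": list(rp.checkpoints),
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_recon(path) -> ReconVolume:
    path = Path(path)
    values = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    meta = json.loads(_sidecar(path).read_text())
    pm = meta["params"]
    params = ReconParams(
        n_subsets=pm["n_subsets"], n_iterations=pm["n_iterations"],
        attenuation=pm["attenuation"], scatter=pm["scatter"], cdr=pm["cdr"],
        checkpoints=tuple(pm["checkpoints"]),
    )
    return ReconVolume(values=values, voxel_size_mm=meta["voxel_size_mm"],
                       params=params, acq_time_total_s=meta["acq_time_total_s"])
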