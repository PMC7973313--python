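"""End-to-end study orchestration at desk scale.

Reproduces the two-phase quantification methodology on procedurally
generated phantoms:

phase 1  optimise OS-EM updates (90% count-recovery criterion), determine
         the sphere and cylinder calibration factors, and build the two
         recovery-coefficient curves at a 6:1 object-to-background ratio
         (kidney RCs computed directly from a dedicated kidney run);
phase 2  quantify four spheres (13:1) in cylinder, torso-like and
         patient-like phantoms plus the two kidneys of the patient-like
         phantom, with and without partial-volume correction, under both
         calibration-factor geometries.

The desk-scale default runs a 64-cube grid at 4.8 mm with 30 projections and
84 OS-EM updates (6 subsets x 14 iterations); acquisitions are noise-free
(the reference study minimised Monte Carlo noise), so results are
deterministic for a given configuration.  A seed is threaded through for the
optional Poisson-noise mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import VoxelGrid, Cylinder
from .phantoms import (
    Phantom, build_cylinder_phantom, build_torso_phantom,
    build_patient_like_phantom, add_sphere, torso_spec, patient_spec,
    sphere_volume,
)
from .acquisition import AcquisitionParams, simulate_acquisition
from .recon import (
    ReconParams, ReconVolume, recovery_trace, updates_to_convergence,
    osem_reconstruct, ConvergenceTrace,
)
from .quantify import (
    CalibrationFactor, RecoveryCurve,
    make_sphere_voi, make_central_cylinder_voi, make_isocontour_voi,
    calibration_factor, recovery_coefficient, fit_rc_curve, eval_rc,
    quantify, percent_difference, summarize, estimate_concentration,
)

__all__ = [
    "StudyConfig", "desk_config", "CalibrationResult", "RcResult",
    "StudyReport", "run_calibration_study", "run_rc_study",
    "run_quantification_study", "run_convergence_study", "run_full_study",
]


@dataclass(frozen=True)
class StudyConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 4.8
    acq: AcquisitionParams = field(default_factory=lambda: AcquisitionParams(
        n_projections=30, matrix=64))
    n_subsets: int = 6
    n_iterations: int = 14            # 84 updates for production recons
    checkpoints: tuple[int, ...] = (24, 48, 84, 120, 168, 204)
    # phase 1
    phase1_conc_mbq_ml: float = 3.04
    rc_ratio: float = 6.0
    rc_diameters_cm: tuple[float, ...] = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
    cal_sphere_diameter_cm: float = 5.0
    central_voi_fractions: tuple[float, float] = (0.5, 0.5)
    # phase 2
    quant_ratio: float = 13.0
    quant_diameters_cm: tuple[float, ...] = (3.1, 3.6, 4.0, 5.0)
    quant_sphere_conc_mbq_ml: float = 2.2
    cylinder_radius_mm: float = 105.0
    cylinder_height_mm: float = 286.0
    # "abdomen next to the liver" pockets: chosen so the largest (5 cm)
    # sphere keeps >= 1.5x the system FWHM of clearance from every organ
    # surface, so neighbouring-organ spill-in does not contaminate the
    # physically-delineated VOI (objects are meant to be separately
    # resolvable, as when spheres are simulated individually).
    torso_sphere_center_mm: tuple[float, float, float] = (-67.0, 0.0, -64.0)
    patient_sphere_center_mm: tuple[float, float, float] = (-58.0, 70.0, -105.0)
    kidney_mask_dilation_vox: int = 2
    noise: bool = False               # Poisson noise on measured projections

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_shape, self.voxel_mm)

    @property
    def recon_params(self) -> ReconParams:
        return ReconParams(n_subsets=self.n_subsets,
                           n_iterations=self.n_iterations)


def desk_config(**overrides) -> StudyConfig:
    """The default desk-scale configuration."""
    return replace(StudyConfig(), **overrides) if overrides else StudyConfig()


def load_study_config(path) -> StudyConfig:
    """Study configuration from a YAML file of overrides.

    Top-level keys mirror StudyConfig fields; `acq` (and `acq.cdr`) are
    nested mappings mirroring AcquisitionParams / CdrModel.  Absent keys
    keep their desk-scale defaults.
    """
    import yaml
    from .projector import CdrModel

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    acq_over = data.pop("acq", None)
    for key in ("grid_shape", "checkpoints", "rc_diameters_cm",
                "quant_diameters_cm", "central_voi_fractions",
                "torso_sphere_center_mm", "patient_sphere_center_mm"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = replace(StudyConfig(), **data)
    if acq_over:
        cdr_over = acq_over.pop("cdr", None)
        acq = replace(cfg.acq, **acq_over)
        if cdr_over:
            acq = replace(acq, cdr=replace(acq.cdr, **cdr_over))
        cfg = replace(cfg, acq=acq)
    return cfg


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _reconstruct(phantom: Phantom, cfg: StudyConfig, seed: int,
                 checkpoints: tuple[int, ...] = ()) -> ReconVolume:
    noise_seed = seed if cfg.noise else None
    measured, scatter_est = simulate_acquisition(phantom, cfg.acq,
                                                 noise_seed=noise_seed)
    if checkpoints:
        n_iter = max(checkpoints) // cfg.n_subsets
        params = ReconParams(n_subsets=cfg.n_subsets, n_iterations=n_iter,
                             checkpoints=checkpoints)
    else:
        params = cfg.recon_params
    return osem_reconstruct(measured, phantom.mu, params,
                            scatter_estimate=scatter_est)


def _kidney_voi(recon: ReconVolume, phantom: Phantom, label: str,
                cfg: StudyConfig):
    """Volume-matched iso-contour VOI restricted to one kidney's vicinity."""
    region = phantom.region(label)
    mask = ndimage.binary_dilation(region.occupancy > 0,
                                   iterations=cfg.kidney_mask_dilation_vox)
    return make_isocontour_voi(recon, region.realized_volume_ml,
                               restrict_mask=mask)


# ---------------------------------------------------------------------------
# phase 1: calibration factors
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    sphere_cf: CalibrationFactor
    cylinder_cf: CalibrationFactor
    percent_difference: float  # (sphere - cylinder) / cylinder x 100

    def cf(self, geometry: str) -> CalibrationFactor:
        return self.sphere_cf if geometry == "sphere" else self.cylinder_cf


def run_calibration_study(cfg: StudyConfig | None = None, seed: int = 0
                          ) -> CalibrationResult:
    """Sphere-CF (hot sphere in cold water) and cylinder-CF (uniform fill)."""
    cfg = cfg or desk_config()
    grid = cfg.grid
    tc = cfg.phase1_conc_mbq_ml
    d_mm = cfg.cal_sphere_diameter_cm * 10.0

    cold = build_cylinder_phantom(grid, cfg.cylinder_radius_mm,
                                  cfg.cylinder_height_mm, background_conc=0.0)
    sphere_phantom = add_sphere(cold, (0.0, 0.0, 0.0), d_mm, tc)
    recon_s = _reconstruct(sphere_phantom, cfg, seed)
    voi_s = make_sphere_voi(grid, (0.0, 0.0, 0.0), d_mm)
    sphere_cf = calibration_factor(recon_s, voi_s, tc,
                                   cfg.acq.total_time_s, geometry="sphere")

    uniform = build_cylinder_phantom(grid, cfg.cylinder_radius_mm,
                                     cfg.cylinder_height_mm, background_conc=tc)
    recon_c = _reconstruct(uniform, cfg, seed + 1)
    voi_c = make_central_cylinder_voi(
        grid,
        Cylinder((0.0, 0.0, 0.0), cfg.cylinder_radius_mm, cfg.cylinder_height_mm),
        *cfg.central_voi_fractions)
    cylinder_cf = calibration_factor(recon_c, voi_c, tc,
                                     cfg.acq.total_time_s, geometry="cylinder")

    diff = percent_difference(sphere_cf.value_cps_per_mbq,
                              cylinder_cf.value_cps_per_mbq, reference="b")
    return CalibrationResult(sphere_cf=sphere_cf, cylinder_cf=cylinder_cf,
                             percent_difference=diff)


# ---------------------------------------------------------------------------
# phase 1: recovery coefficients
# ---------------------------------------------------------------------------

@dataclass
class RcResult:
    curves: dict[str, RecoveryCurve]        # per CF geometry
    points: pd.DataFrame                    # diameter, volume, RC per geometry
    kidney_rc: dict[str, dict[str, float]]  # label -> geometry -> RC
    table1: pd.DataFrame

    def rc_for_sphere(self, geometry: str, diameter_cm: float) -> float:
        return float(eval_rc(self.curves[geometry], diameter_cm))


def run_rc_study(cal: CalibrationResult, cfg: StudyConfig | None = None,
                 seed: int = 10) -> RcResult:
    """Eight-sphere RC curves (6:1) per CF plus direct kidney RCs."""
    cfg = cfg or desk_config()
    grid = cfg.grid
    tc = cfg.phase1_conc_mbq_ml
    bg = tc / cfg.rc_ratio
    t_total = cfg.acq.total_time_s

    rows = []
    for j, d_cm in enumerate(cfg.rc_diameters_cm):
        d_mm = d_cm * 10.0
        phantom = build_cylinder_phantom(grid, cfg.cylinder_radius_mm,
                                         cfg.cylinder_height_mm,
                                         background_conc=bg)
        phantom = add_sphere(phantom, (0.0, 0.0, 0.0), d_mm, tc)
        recon = _reconstruct(phantom, cfg, seed + j)
        voi = make_sphere_voi(grid, (0.0, 0.0, 0.0), d_mm)
        row = {"diameter_cm": d_cm, "volume_ml": sphere_volume(d_cm)}
        for geom in ("sphere", "cylinder"):
            c_spect = estimate_concentration(recon, voi, cal.cf(geom), t_total)
            row[f"rc_{geom}"] = recovery_coefficient(c_spect, tc)
        rows.append(row)
    points = pd.DataFrame(rows)

    curves = {
        geom: fit_rc_curve(points[["diameter_cm", f"rc_{geom}"]].to_numpy(),
                           cf_geometry=geom)
        for geom in ("sphere", "cylinder")
    }

    # dedicated kidney run: kidneys hot at the phase-1 concentration, all
    # other compartments at the 6:1 background
    spec = patient_spec(liver_conc=bg, lung_conc=bg, spleen_conc=bg,
                        kidney_conc=tc, background_conc=bg)
    kidney_phantom = build_patient_like_phantom(grid, spec)
    recon_k = _reconstruct(kidney_phantom, cfg, seed + 100)
    kidney_rc: dict[str, dict[str, float]] = {}
    for label in ("kidney_left", "kidney_right"):
        voi = _kidney_voi(recon_k, kidney_phantom, label, cfg)
        kidney_rc[label] = {}
        for geom in ("sphere", "cylinder"):
            c_spect = estimate_concentration(recon_k, voi, cal.cf(geom), t_total)
            kidney_rc[label][geom] = recovery_coefficient(c_spect, tc)

    table1 = _table1(cfg, curves, kidney_rc)
    return RcResult(curves=curves, points=points, kidney_rc=kidney_rc,
                    table1=table1)


def _table1(cfg, curves, kidney_rc) -> pd.DataFrame:
    rows = []
    for label, rcs in kidney_rc.items():
        rows.append({"object": label, "sphere_rc": rcs["sphere"],
                     "cylinder_rc": rcs["cylinder"]})
    for d_cm in cfg.quant_diameters_cm:
        rows.append({
            "object": f"sphere {sphere_volume(d_cm):.1f} ml",
            "sphere_rc": float(eval_rc(curves["sphere"], d_cm)),
            "cylinder_rc": float(eval_rc(curves["cylinder"], d_cm)),
        })
    df = pd.DataFrame(rows)
    df["pct_difference"] = [
        percent_difference(s, c, reference="a")
        for s, c in zip(df.sphere_rc, df.cylinder_rc)
    ]
    return df


# ---------------------------------------------------------------------------
# phase 2: quantification error
# ---------------------------------------------------------------------------

def _quant_phantom(name: str, cfg: StudyConfig, d_cm: float | None) -> tuple[Phantom, tuple]:
    """Phantom for one quantification run; d_cm None means no sphere insert."""
    grid = cfg.grid
    conc = cfg.quant_sphere_conc_mbq_ml
    if name == "cylinder":
        base = build_cylinder_phantom(grid, cfg.cylinder_radius_mm,
                                      cfg.cylinder_height_mm,
                                      background_conc=conc / cfg.quant_ratio)
        center = (0.0, 0.0, 0.0)
    elif name == "torso":
        base = build_torso_phantom(grid, torso_spec())
        center = cfg.torso_sphere_center_mm
    elif name == "patient":
        base = build_patient_like_phantom(grid, patient_spec())
        center = cfg.patient_sphere_center_mm
    else:
        raise ValueError(name)
    if d_cm is None:
        return base, center
    return add_sphere(base, center, d_cm * 10.0, conc), center


def run_quantification_study(cal: CalibrationResult, rc: RcResult,
                             cfg: StudyConfig | None = None, seed: int = 1000,
                             phantoms: tuple[str, ...] = ("cylinder", "torso", "patient"),
                             ) -> dict[str, pd.DataFrame]:
    """Quantification error tables per phantom (spheres, plus kidneys in the
    patient-like phantom) for the four CF / CF-RC combinations."""
    cfg = cfg or desk_config()
    grid = cfg.grid
    t_total = cfg.acq.total_time_s
    conc = cfg.quant_sphere_conc_mbq_ml
    tables: dict[str, pd.DataFrame] = {}
    run = 0
    for name in phantoms:
        rows = []
        for d_cm in cfg.quant_diameters_cm:
            phantom, center = _quant_phantom(name, cfg, d_cm)
            recon = _reconstruct(phantom, cfg, seed + run)
            run += 1
            voi = make_sphere_voi(grid, center, d_cm * 10.0)
            row = {"object": f"{sphere_volume(d_cm):.1f} ml",
                   "diameter_cm": d_cm}
            for geom in ("sphere", "cylinder"):
                q0 = quantify(recon, voi, cal.cf(geom), t_total, conc)
                qpvc = quantify(recon, voi, cal.cf(geom), t_total, conc,
                                rc=rc.rc_for_sphere(geom, d_cm))
                row[f"{geom}_cf"] = q0.error_pct
                row[f"{geom}_cf_rc"] = qpvc.error_pct
            rows.append(row)
        tables[name] = _with_summary(pd.DataFrame(rows))

    if "patient" in phantoms:
        phantom, _ = _quant_phantom("patient", cfg, None)
        recon = _reconstruct(phantom, cfg, seed + 900)
        rows = []
        for label in ("kidney_left", "kidney_right"):
            region = phantom.region(label)
            voi = _kidney_voi(recon, phantom, label, cfg)
            row = {"object": label, "diameter_cm": np.nan}
            for geom in ("sphere", "cylinder"):
                q0 = quantify(recon, voi, cal.cf(geom), t_total,
                              region.concentration_mbq_ml)
                qpvc = quantify(recon, voi, cal.cf(geom), t_total,
                                region.concentration_mbq_ml,
                                rc=rc.kidney_rc[label][geom])
                row[f"{geom}_cf"] = q0.error_pct
                row[f"{geom}_cf_rc"] = qpvc.error_pct
            rows.append(row)
        tables["patient_kidneys"] = _with_summary(pd.DataFrame(rows))
    return tables


_ERROR_COLS = ("sphere_cf", "sphere_cf_rc", "cylinder_cf", "cylinder_cf_rc")


def _with_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Append signed and absolute average +/- sample-SD rows."""
    out = df.copy()
    for mode, tag in (("signed", "average"), ("absolute", "average_abs")):
        row = {"object": tag, "diameter_cm": np.nan}
        for col in _ERROR_COLS:
            mean, sd = summarize(df[col].to_numpy(), mode=mode)
            row[col] = mean
            row[f"{col}_sd"] = sd
        out = pd.concat([out, pd.DataFrame([row])], ignore_index=True)
    return out


def max_abs_pvc_error(tables: dict[str, pd.DataFrame]) -> float:
    """Largest |error| over all objects and both matched CF-RC combinations."""
    worst = 0.0
    for df in tables.values():
        rows = df[~df.object.str.startswith("average")]
        for col in ("sphere_cf_rc", "cylinder_cf_rc"):
            worst = max(worst, float(rows[col].abs().max()))
    return worst


# ---------------------------------------------------------------------------
# phase 1: convergence optimisation
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceStudyResult:
    traces: dict[str, ConvergenceTrace]
    updates_per_object: dict[str, int]
    chosen_updates: int
    unconverged: tuple[str, ...] = ()


def run_convergence_study(cfg: StudyConfig | None = None, seed: int = 500,
                          sphere_volumes_ml: tuple[float, ...] = (4.2, 14.1, 65.4),
                          ratios: tuple[float, ...] = (13.0,),
                          include_kidneys: bool = True,
                          threshold_pct: float = 90.0) -> ConvergenceStudyResult:
    """Percentage-recovery traces vs OS-EM updates for different object sizes.

    Returns per-object traces (recovery normalised at the last checkpoint,
    default 204 updates) and the first checkpoint at which every object has
    recovered `threshold_pct` of its counts.
    """
    cfg = cfg or desk_config()
    grid = cfg.grid
    tc = cfg.phase1_conc_mbq_ml
    traces: dict[str, ConvergenceTrace] = {}
    ups: dict[str, int] = {}
    unconverged = []
    run = 0
    for ratio in ratios:
        bg = tc / ratio
        for vol in sphere_volumes_ml:
            d_cm = (6.0 * vol / np.pi) ** (1.0 / 3.0)
            phantom = build_cylinder_phantom(grid, cfg.cylinder_radius_mm,
                                             cfg.cylinder_height_mm,
                                             background_conc=bg)
            phantom = add_sphere(phantom, (0.0, 0.0, 0.0), d_cm * 10.0, tc)
            recon = _reconstruct(phantom, cfg, seed + run,
                                 checkpoints=cfg.checkpoints)
            run += 1
            voi = make_sphere_voi(grid, (0.0, 0.0, 0.0), d_cm * 10.0)
            label = f"sphere {vol:g} ml ({ratio:g}:1)"
            traces[label] = recovery_trace(recon.checkpoints, voi.weights,
                                           label=label)
        if include_kidneys:
            spec = patient_spec(liver_conc=bg, lung_conc=bg, spleen_conc=bg,
                                kidney_conc=tc, background_conc=bg)
            phantom = build_patient_like_phantom(grid, spec)
            recon = _reconstruct(phantom, cfg, seed + run,
                                 checkpoints=cfg.checkpoints)
            run += 1
            final = max(cfg.checkpoints)
            for side in ("kidney_left", "kidney_right"):
                final_vol = recon.checkpoints[final]
                voi = make_isocontour_voi(
                    final_vol, phantom.region(side).realized_volume_ml,
                    voxel_volume_ml=grid.voxel_volume_ml,
                    restrict_mask=ndimage.binary_dilation(
                        phantom.region(side).occupancy > 0,
                        iterations=cfg.kidney_mask_dilation_vox))
                label = f"{side} ({ratio:g}:1)"
                traces[label] = recovery_trace(recon.checkpoints, voi.weights,
                                               label=label)
    for label, tr in traces.items():
        try:
            ups[label] = updates_to_convergence(tr, threshold_pct)
        except Exception:
            unconverged.append(label)
    chosen = max(ups.values()) if ups else 0
    return ConvergenceStudyResult(traces=traces, updates_per_object=ups,
                                  chosen_updates=chosen,
                                  unconverged=tuple(unconverged))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    config: StudyConfig
    seed: int
    calibration: CalibrationResult
    rc: RcResult
    quant_tables: dict[str, pd.DataFrame]
    convergence: ConvergenceStudyResult | None = None

    @property
    def max_abs_pvc_error_pct(self) -> float:
        return max_abs_pvc_error(self.quant_tables)


def run_full_study(seed: int = 1, cfg: StudyConfig | None = None,
                   include_convergence: bool = False) -> StudyReport:
    """Calibration + RC + quantification (optionally also the convergence
    experiment) under one seed."""
    cfg = cfg or desk_config()
    cal = run_calibration_study(cfg, seed=seed)
    rc = run_rc_study(cal, cfg, seed=seed + 10)
    tables = run_quantification_study(cal, rc, cfg, seed=seed + 1000)
    conv = run_convergence_study(cfg, seed=seed + 500) if include_convergence else None
    return StudyReport(config=cfg, seed=seed, calibration=cal, rc=rc,
                       quant_tables=tables, convergence=conv)
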