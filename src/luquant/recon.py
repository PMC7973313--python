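"""3D OS-EM reconstruction with attenuation, scatter and CDR compensation,
plus the convergence (percentage recovery) and noise (%RMS) analyses.

The reconstruction uses the same rotation-based system model as the
acquisition simulation.  Voxel values are calibrated such that a VOI's
weighted sum equals the total counts attributable to that VOI over the whole
scan, which is the natural input to the count-rate based calibration factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .acquisition import ProjectionSet, build_system_model
from .projector import SystemModel

__all__ = [
    "ReconParams", "ReconVolume", "ConvergenceTrace",
    "osem_core", "osem_reconstruct",
    "percent_rms", "recovery_trace", "updates_to_convergence",
    "NotConvergedError",
]

DENOM_EPS = 1e-12


class NotConvergedError(RuntimeError):
    """Recovery threshold was never reached within the traced updates."""


@dataclass(frozen=True)
class ReconParams:
    """OS-EM settings; updates = n_subsets * n_iterations.

    Subsets are angle-interleaved in a fixed order (subset k takes angles
    k, k+n_subsets, ...), which keeps the update sequence deterministic.
    """

    n_subsets: int = 6
    n_iterations: int = 14
    attenuation: bool = True
    scatter: bool = True
    cdr: bool = True
    checkpoints: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_subsets < 1 or self.n_iterations < 1:
            raise ValueError("subsets and iterations must be >= 1")
        bad = [c for c in self.checkpoints if c < 1 or c > self.updates]
        if bad:
            raise ValueError(f"checkpoints outside 1..updates: {bad}")

    @property
    def updates(self) -> int:
        return self.n_subsets * self.n_iterations


@dataclass
class ReconVolume:
    """Reconstructed counts per voxel with provenance."""

    values: np.ndarray
    voxel_size_mm: float
    params: ReconParams
    acq_time_total_s: float
    checkpoints: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("reconstruction must be finite and non-negative")


@dataclass
class ConvergenceTrace:
    """Per-checkpoint VOI recovery and noise metrics."""

    updates: np.ndarray        # checkpoint update counts, increasing
    voi_counts: np.ndarray     # weighted VOI totals
    recovery_pct: np.ndarray   # normalised to the final checkpoint
    rms_pct: np.ndarray        # Eq-style 100*SD/mean within the VOI
    label: str = ""


def osem_core(projections, subsets, forward_one, back_one, sensitivities,
              x0, n_iterations, scatter=None, checkpoints=(),
              callback=None):
    """Generic ordered-subset EM loop.

    projections: sequence of per-angle data arrays.
    subsets: list of angle-index lists, processed in order; one subset pass
    is one update.  forward_one(x, i) / back_one(r, i) implement the system
    matrix row block for angle i; sensitivities[k] is the backprojection of
    ones over subset k.  scatter, when given, is added to the forward
    projection in the denominator (additive model-based correction).
    With a single subset this reduces exactly to MLEM.
    """
    x = np.array(x0, dtype=np.float32)
    if np.any(x < 0):
        raise ValueError("initial estimate must be non-negative")
    snapshots = {}
    update = 0
    for _ in range(n_iterations):
        for k, idx in enumerate(subsets):
            ratio_back = np.zeros_like(x)
            for i in idx:
                expected = forward_one(x, i)
                if scatter is not None:
                    expected = expected + scatter[i]
                expected = np.maximum(expected, DENOM_EPS)
                ratio_back += back_one(projections[i] / expected, i)
            sens = sensitivities[k]
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.where(sens > 0, x * ratio_back / np.maximum(sens, DENOM_EPS), 0.0)
            x = x.astype(np.float32)
            update += 1
            if update in checkpoints:
                snapshots[update] = x.copy()
            if callback is not None:
                callback(update, x)
    return x, snapshots


def _interleaved_subsets(n_projections: int, n_subsets: int):
    if n_projections % n_subsets != 0:
        raise ValueError(
            f"{n_projections} projections not divisible by {n_subsets} subsets")
    return [list(range(k, n_projections, n_subsets)) for k in range(n_subsets)]


def osem_reconstruct(projections: ProjectionSet, mu_map, params: ReconParams,
                     scatter_estimate: ProjectionSet | None = None,
                     model: SystemModel | None = None) -> ReconVolume:
    """OS-EM with the acquisition's own system model.

    The estimate is initialised uniformly inside the attenuation support and
    scaled so that voxel values are total-scan counts; the per-angle forward
    model therefore carries a 1/n_projections factor.
    """
    counts = np.asarray(projections.counts, dtype=np.float32)
    n_proj = counts.shape[0]
    subsets = _interleaved_subsets(n_proj, params.n_subsets)

    if params.scatter and scatter_estimate is not None:
        scat = np.asarray(scatter_estimate.counts, dtype=np.float32)
        if np.any(scat < 0):
            raise ValueError("scatter estimate must be non-negative")
    else:
        scat = None

    if model is None:
        grid_shape = (counts.shape[1], counts.shape[1], counts.shape[2])
        model = build_system_model(
            grid_shape, projections.params.pixel_mm, projections.orbit,
            projections.params,
            mu=mu_map if params.attenuation else None,
            include_cdr=params.cdr,
        )

    # per-angle operator for total-scan counts
    def forward_one(x, i):
        return model.project_one(x, i) / n_proj

    def back_one(r, i):
        return model.backproject_one(r, i) / n_proj

    sens = [model.sensitivity(idx) / n_proj for idx in subsets]

    support = (np.asarray(mu_map) > 0) if mu_map is not None else np.ones(model.shape, bool)
    total = float(counts.sum())
    x0 = np.zeros(model.shape, dtype=np.float32)
    n_support = int(support.sum())
    if n_support > 0 and total > 0:
        x0[support] = total / n_support

    x, snaps = osem_core(counts, subsets, forward_one, back_one, sens,
                         x0, params.n_iterations, scatter=scat,
                         checkpoints=set(params.checkpoints))
    return ReconVolume(
        values=np.asarray(x, dtype=np.float64),
        voxel_size_mm=model.voxel_size_mm,
        params=params,
        acq_time_total_s=projections.params.total_time_s,
        checkpoints={u: np.asarray(v, dtype=np.float64) for u, v in snaps.items()},
    )


# ---------------------------------------------------------------------------
# noise and convergence metrics
# ---------------------------------------------------------------------------

def percent_rms(values: np.ndarray, voi_weights: np.ndarray,
                min_weight: float = 0.5) -> float:
    """Noise metric: 100 * sample SD / mean of the voxel counts in a VOI.

    Voxels with fractional weight >= min_weight form the statistical sample
    (SD over partially-covered edge voxels would mix geometry into the noise
    estimate).  Sample SD uses the n-1 convention.
    """
    values = getattr(values, "values", values)  # accept a ReconVolume
    vox = np.asarray(values)[np.asarray(voi_weights) >= min_weight]
    if vox.size < 2:
        raise ValueError("VOI too small for a noise estimate")
    mean = float(vox.mean())
    if mean == 0:
        raise ValueError("%RMS undefined for zero-mean VOI")
    sd = float(vox.std(ddof=1))
    return 100.0 * sd / mean


def recovery_trace(checkpoint_volumes: dict[int, np.ndarray],
                   voi_weights: np.ndarray, final_updates: int | None = None,
                   label: str = "", normalize_rms: bool = False) -> ConvergenceTrace:
    """Percentage count recovery (and %RMS) per checkpoint.

    Recovery is the VOI total normalised to its value at the final
    checkpoint, mirroring the convention of normalising to the counts at the
    maximum number of updates.
    """
    if not checkpoint_volumes:
        raise ValueError("no checkpoints")
    ups = np.array(sorted(checkpoint_volumes), dtype=int)
    final = int(ups.max()) if final_updates is None else int(final_updates)
    if final not in checkpoint_volumes:
        raise ValueError(f"final checkpoint {final} missing from trace")
    w = np.asarray(voi_weights)
    counts = np.array([float((checkpoint_volumes[u] * w).sum()) for u in ups])
    ref = float((checkpoint_volumes[final] * w).sum())
    if ref <= 0:
        raise ValueError("zero VOI counts at the final checkpoint")
    rms = np.array([percent_rms(checkpoint_volumes[u], w) for u in ups])
    if normalize_rms:
        ref_rms = rms[ups == final][0]
        rms = 100.0 * rms / ref_rms
    return ConvergenceTrace(updates=ups, voi_counts=counts,
                            recovery_pct=100.0 * counts / ref,
                            rms_pct=rms, label=label)


def updates_to_convergence(trace: ConvergenceTrace, threshold_pct: float = 90.0) -> int:
    """Smallest traced update count whose recovery meets the threshold."""
    if trace.updates.size == 0:
        raise ValueError("empty trace")
    ok = trace.recovery_pct >= threshold_pct
    if not ok.any():
        raise NotConvergedError(
            f"recovery never reached {threshold_pct}% "
            f"(max {trace.recovery_pct.max():.1f}%)")
    return int(trace.updates[ok.argmax()])
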