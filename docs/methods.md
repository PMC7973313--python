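# Methods

`luquant` reproduces, on fully synthetic data, a quantitative ¹⁷⁷Lu SPECT
methodology: how the choice of calibration-factor (CF) geometry and its
matched recovery coefficients (RC) propagates into activity-quantification
error. This note documents the models, the parameters that matter, and the
choices made where the design was genuinely open.

## Imaging model

### Phantoms

Phantoms are paired voxel maps — activity (MBq/ml) and linear attenuation
(cm⁻¹) — plus a region truth table. Three geometries are provided:

* **Cylinder** — radius 105 mm × height 286 mm (9900 ml) of water, used for
  calibration, RC determination and the simple-geometry quantification runs.
* **Torso-like** — an elliptic-cylinder activity-fillable body (5275 ml
  gross) containing two elliptic-cylinder lungs (1045 ml each, lung-density
  attenuation) above an elliptic-cylinder liver (1090 ml); the soft-tissue
  remainder is 2095 ml. A water-equivalent, activity-free shell
  (280 × 190 × 260 mm) surrounds the compartments: physical torso phantoms
  are human-scale attenuating objects of which only the fillable
  compartments carry activity, and without the shell the spheres sit
  unrealistically shallow, invert the torso-vs-cylinder error trend and
  see too little attenuation.
* **Patient-like** — an elliptic-cylinder body whose remainder is 14,100 ml,
  with ellipsoidal lungs (2 × 1135 ml), liver (1590 ml), spleen (160 ml) and
  kidneys (159/169 ml).

Shapes are analytic solids rasterized by deterministic per-voxel
supersampling. The supersampling factor adapts to object size (15³ for
solids under ~16 voxels across, down to 5³ for bodies), and compartment
solids get a one-or-two-step volume-matching rescale of a free axis, so
every region's realized volume is within 1% (organs typically within 0.1%)
of its target. Sphere inserts mix boundary voxels by fractional occupancy
and may not touch other inserts; each object was simulated individually in
the reference design to avoid neighbour spill-in, and the builders enforce
that.

Attenuation defaults are physical estimates at the 208 keV photopeak:
0.136 cm⁻¹ for water-equivalent tissue, 0.041 cm⁻¹ for inflated lung
(≈0.3 g/ml). They are config constants, not fitted values.

### Acquisition

Photon transport is replaced by an analytic rotation-based projector:

* parallel-beam geometry, volume rotated per angle (linear interpolation,
  zero outside the grid), detector along +y;
* attenuation by the cumulative μ-integral toward the detector with a
  half-voxel offset at the emission voxel (Beer–Lambert exact to <1% in
  closed-form tests);
* collimator-detector response (CDR) as a per-layer 2-D Gaussian with
  FWHM(d) = c₀ + c₁·d; the default (c₁ = 0.07, FWHM = 11 mm at the 10 cm
  reference distance) matches the 1.1 cm planar resolution of a
  medium-energy collimator. The reference distance is not a measured
  quantity and is exposed in the config;
* a single scalar system sensitivity S (default 14 cps/MBq in the
  photopeak) absorbs all energy-window physics;
* an auto-contour non-circular orbit: per angle, the support extent of the
  attenuation map toward the detector plus a 20 mm margin;
* scatter as one broad unit-sum Gaussian kernel (FWHM 80 mm) applied to the
  primary per angle and normalised globally so scatter/(primary+scatter)
  equals the scatter fraction (default 0.2) exactly. The same scatter plane
  is the additive term of the reconstruction's forward model — a
  self-consistent, model-based scatter-correction scenario, mirroring how a
  kernel-based correction is used inside the reference reconstruction;
* optional Poisson noise with an explicit seed. The study defaults are
  noise-free, emulating the "high number of photon histories" regime; the
  noise path exists for the %RMS analyses.

A deliberately simplified stand-in: no septal penetration, no energy
spectra, no dead time, single head. Because simulation and reconstruction
share one forward model, the study isolates the *geometry logic* of
CF/RC-based quantification (spill-in/spill-out, VOI definition, ratio
mismatch) rather than correction-model mismatch; absolute error levels on
real cameras will be higher.

### Reconstruction

Standard OS-EM with angle-interleaved, fixed-order subsets. The forward
model in the update is the acquisition model itself (attenuation, CDR and
additive scatter per toggles); backprojection is its adjoint with the
rotation adjoint approximated by the inverse rotation (the usual
rotator-projector pairing). Initialisation is a uniform positive value
inside the attenuation support (zero outside, which multiplicative updates
preserve); denominators are clamped at 1e-12. Voxel values are calibrated
as total-scan counts, so a VOI's weighted sum is the count total that
enters the count-rate formula. With one subset the loop is exactly MLEM
(verified against hand iterates on a 2-voxel system).

Defaults: 6 subsets × 14 iterations = 84 updates, the production setting
selected by the 90%-recovery convergence criterion; the convergence
experiment traces checkpoints {24, 48, 84, 120, 168, 204} (all divisible by
6, recovery normalised at 204).

## Quantification chain

* **VOIs.** Sphere VOIs use the object's physical dimensions with
  fractional voxel weights (counts = Σ weight × voxel value). The
  cylinder-CF VOI is a coaxial cylinder at half radius/half height,
  keeping >2×FWHM from all edges. Kidney VOIs are volume-matched
  iso-contours: a binary threshold found on the sorted voxel-value axis so
  the VOI volume matches the true kidney volume within half a voxel,
  searched inside the true kidney mask dilated by 2 voxels (unrestricted
  thresholding would capture liver voxels, which are hotter than kidney in
  the clinical distribution; the reference analysis drew per-kidney
  contours interactively).
* **Calibration factors.** CF = (CR/V)/TC with CR = VOI counts / total scan
  time. Sphere-CF: 65.4 ml sphere at 3.04 MBq/ml in the cold water
  cylinder. Cylinder-CF: uniform 3.04 MBq/ml fill, central VOI. Spill-out
  makes the sphere-CF smaller; the percent difference is reported with the
  cylinder-CF as reference.
* **Recovery coefficients.** RC = C_SPECT/C_true for eight spheres
  (1.5–5.0 cm) at 6:1, fitted per CF by y = a − b·e^(−cx) (least squares,
  b ≥ 0, c > 0; degenerate all-equal input collapses to a = y, b = 0 with a
  flagged non-identifiable rate). Quantified spheres take their RC from the
  fitted curve; kidneys take theirs directly from a dedicated run
  (patient-like phantom, kidneys at 3.04 MBq/ml over a 6:1 background,
  other organs at background), because sphere-based look-ups transfer
  poorly to renal geometry.
* **Errors.** Quantification error (%) = 100·(C_SPECT − C_true)/C_true;
  summaries report mean ± sample SD (n−1 everywhere, validated against the
  published ±2.67), in signed and mean-of-absolute-values ("absolute
  average") modes; an SD over a single value is reported as undefined, not
  zero. RCs are carried at full precision internally; tables round to two
  decimals.

An exact algebraic consequence worth stating: for any object measured on
one reconstruction, RC(sphere-CF)/RC(cylinder-CF) equals the inverse CF
ratio, so matched CF-RC corrected concentrations are identical by
construction — the comparability of the two CF-RC combinations is a
structural property, and the interesting question is the *size* of the
residual error, driven by the RC-curve fit residual and by the 6:1 → 13:1
ratio mismatch between the RC determination and the evaluation (a
deliberate design mismatch, mirrored here).

## Study conditions (desk scale)

The default configuration runs everything on a 64³ grid at 4.8 mm with 30
projections of 45 s and 84 updates — sized so the complete pipeline
(24 reconstructions) finishes in minutes on one CPU. The clinical protocol
(128 matrix, 60 projections) is available through the config. Problem
sizes: 2 calibration runs, 8 RC spheres + 1 kidney-RC run, 12 sphere
quantification runs + 1 kidney quantification run; the convergence
experiment adds traces to 204 updates.

Concentrations mirror the reference conditions: phase 1 at 3.04 MBq/ml;
quantification spheres at 2.2 MBq/ml with 13:1 sphere-to-background;
torso lungs/liver/remainder at 0.34/0.51/0.17 MBq/ml; patient
liver/lungs/spleen/kidneys/remainder at 0.51/0.34/0.52/0.45/0.02 MBq/ml
(kidney-to-background 22.5, quoted as "23:1"; reports use the realized
ratio).

Open placements decided here: the torso and patient quantification spheres
sit in the abdomen next to the liver at positions chosen so the largest
(5 cm) sphere keeps at least 1.5× the system FWHM of clearance from every
organ surface — close enough to share the liver's attenuation environment,
far enough that the physically-delineated VOI is not contaminated by
neighbour spill-in (the same rationale behind simulating objects
individually). The printed "2.4 ml (1.5 cm)" smallest RC sphere is
internally inconsistent ((4/3)π·0.75³ = 1.77 ml); diameters are treated as
authoritative since they are the RC-curve abscissa.

## Numerical choices

* Rotation: linear interpolation, no prefilter; a single-voxel delta does
  not resample conservatively, so "point sources" in tests are 1.5-voxel
  Gaussian blobs (conservation then holds to ~0.1%).
* Iso-contour threshold ties are trimmed deterministically (array order) to
  land within half a voxel of the target volume.
* %RMS uses voxels with VOI weight ≥ 0.5, keeping partial-edge voxels from
  mixing geometry into the noise statistic.
* Degenerate inputs error loudly: grids under 8 voxels per axis, shapes
  exceeding the grid (named axis), overlapping inserts, empty density maps,
  scatter fraction ≥ 1, subset counts not dividing the projection count,
  unreachable iso-contour volumes, zero-mean %RMS VOIs.

## What passing tests do and do not show

The generator emulates segmented-CT voxel phantoms with uniform
compartment concentrations and a validated-camera-like response; it does
not emulate septal penetration tails, non-uniform intra-organ uptake,
misregistration between emission and anatomy, or camera-specific
reconstruction products. Passing the suite shows the quantification logic
(CF/RC algebra, VOI conventions, convergence behaviour, partial-volume
trends) is implemented faithfully and behaves as reported under matched
forward models; it does not certify absolute accuracy numbers for any
physical camera.

## Known limitations

* The adjoint pairing (inverse-rotation backprojection) is inexact at the
  interpolation level; count totals at the fixed point agree with the data
  to well under 2%, but bitwise fixed-point properties should not be
  expected.
* Desk-scale angular sampling (30 views) leaves mild streaking near the
  cylinder edge; the central-VOI convention makes the cylinder-CF
  insensitive to it.
* Kidney RCs require knowing the true concentration — a phantom-only
  luxury, acknowledged as such in the source methodology.
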