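# luquant

Desk-scale quantitative ¹⁷⁷Lu SPECT pipeline: how the choice of
calibration-factor geometry — and the recovery coefficients derived with it —
propagates into activity-quantification error.

¹⁷⁷Lu radionuclide therapy (e.g. DOTATATE for neuroendocrine tumours) needs
patient-specific dosimetry, which needs SPECT images converted from counts
into MBq/ml. There is no consensus on the calibration-factor (CF) geometry
used for that conversion. This package implements, end to end on synthetic
data, the comparison of two common choices:

* **sphere-CF** — a hot 65.4 ml sphere in non-radioactive water, delineated
  at its physical dimensions (spill-out makes it low);
* **cylinder-CF** — a uniformly filled cylinder with a central volume of
  interest (edge effects excluded).

For each CF, recovery coefficients RC = C_SPECT/C_true are measured for
eight spheres (1.5–5.0 cm) at a 6:1 sphere-to-background ratio and fitted by
the mono-exponential curve

    RC(x) = a − b·e^(−c·x),    x = sphere diameter (cm),

while kidney RCs are computed directly from a dedicated kidney simulation.
The quantification error of four spheres (13:1) in three phantoms — a
cylinder, a torso-like and a patient-like phantom — plus the patient's two
kidneys is then evaluated as

    error (%) = 100 · (C_SPECT − C_true) / C_true,

without partial-volume correction and with PVC (dividing by the matched RC),
with CF = (CR/V)/TC in cps/MBq. Everything upstream is implemented too:
procedural voxel phantoms with volume-exact organs, an analytic attenuated
projector with distance-dependent collimator response and kernel-based
scatter, a non-circular auto-contour orbit, and 3D OS-EM reconstruction with
attenuation, scatter and CDR compensation (84 updates = 6 subsets × 14
iterations, selected by a 90% count-recovery convergence criterion).

Intended audience: medical-physics and image-quantification researchers who
want a transparent, fully testable sandbox for CF/RC methodology — not a
camera simulator.

## Worked example

```python
from luquant import run_full_study

report = run_full_study(seed=1)
cal = report.calibration
print(f"sphere-CF   {cal.sphere_cf.value_cps_per_mbq:.2f} cps/MBq")
print(f"cylinder-CF {cal.cylinder_cf.value_cps_per_mbq:.2f} cps/MBq "
      f"({cal.percent_difference:+.1f}%)")
print(report.rc.points.round(3))
print(report.quant_tables["cylinder"].round(2))
print(f"max |error| with PVC: {report.max_abs_pvc_error_pct:.2f}%")
```

prints (desk-scale defaults: 64³ grid at 4.8 mm, 30 views × 45 s,
noise-free):

```
sphere-CF   12.43 cps/MBq
cylinder-CF 14.00 cps/MBq (-11.2%)
   diameter_cm  volume_ml  rc_sphere  rc_cylinder
0          1.5      1.767      0.463        0.411
1          2.0      4.189      0.697        0.619
...
7          5.0     65.450      0.969        0.860
        object  diameter_cm  sphere_cf  sphere_cf_rc  cylinder_cf  cylinder_cf_rc
0      15.6 ml          3.1     -12.75         -1.48       -22.55           -1.48
1      24.4 ml          3.6     -10.58         -2.67       -20.63           -2.67
2      33.5 ml          4.0      -7.36         -0.84       -17.77           -0.84
3      65.4 ml          5.0      -3.24          1.64       -14.11            1.64
4      average         NaN       -8.48         -0.84       -18.76           -0.84
5  average_abs         NaN        8.48          1.66        18.76            1.66
max |error| with PVC: 3.80%
```

Reading it: the sphere-CF sits below the cylinder-CF because counts spill
out of the physically-sized calibration VOI; without PVC the cylinder-CF
consequently underestimates every sphere by ~14–23% while the sphere-CF
errors are much smaller; and after partial-volume correction the two matched
CF-RC combinations give *identical* errors (an exact algebraic property —
the RC ratio cancels the CF ratio), within a few percent of truth. Kidneys
show the opposite geometry preference: the sphere-CF overestimates them
without PVC, and with PVC both combinations land within 1%.

The numbered scripts under `analysis/` run the same phases as standalone
drivers (`01_build_phantoms.py` … `05_quantification.py`) and write their
tables under `results/`.

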