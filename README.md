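# bhctvi — breath-hold CT ventilation imaging on synthetic thorax phantoms

`bhctvi` implements deformable-image-registration (DIR) based breath-hold CT
ventilation imaging (BH-CTVI) as a reusable, fully testable pipeline. It is
aimed at medical-physics and image-analysis researchers who want to study how
body position (supine, prone, right/left lateral decubitus) shapes regional
lung ventilation estimates — without access to volunteer CT scans. A
synthetic breathing-thorax phantom with an *analytically known* deformation
stands in for the scans, so every stage of the pipeline can be validated
against exact ground truth.

## The method

Given an expiration-phase CT (fixed reference) and an inspiration-phase CT,
DIR estimates the displacement field **u**(x, y, z) mapping each expiration
voxel to its inspiration position. The ventilation surrogate is the Jacobian
determinant of the transform,

```
V(x, y, z) = det(I + ∇u),
```

the local volume-change factor: V > 1 expansion, V < 1 contraction, V = 1
neither. Within the segmented lungs V is converted to percentiles of the
in-lung distribution, and voxels at or above the **75th percentile** are
classified *highly functional*. The fraction of highly functional voxels is
reported per lung for four cranio-caudal sections (apical, middle, basal,
diaphragm), and displacement orientation is summarised by a
magnitude-weighted gravity-alignment index (Σ u·ĝ / Σ |u|) and a
ground-parallelism index (mean √(1 − (û·ĝ)²)). Across a cohort, section
ratios are compared between positions with exact Wilcoxon signed-rank tests
at the Bonferroni-adjusted threshold α/3 = 0.05/3 (displayed 0.016).

The registration is an in-package multi-resolution cubic B-spline free-form
deformation: coefficients on a coarse control lattice, dense SSD (or NCC, or
tissue-volume-preserving SSD) metric with analytic gradients, L-BFGS-B
optimisation, and a physically scaled curvature penalty — deterministic by
construction (no stochastic sampling).

The phantom provides paired exhale/inhale volumes in Hounsfield units with
lungs, body, and spine, multi-scale parenchymal texture, partial-volume
edges, gas-density rescaling (HU' = −1000 + (HU + 1000)/J), and a
ground-truth displacement whose Jacobian is known in closed form inside the
lungs: mean lung expansion 1.30 (a typical tidal volume ratio), with linear
expansion gradients along gravity (dependent side higher) and toward the
diaphragm. See `docs/methods.md` for the construction.

## Worked example

The analysis chain on a supine phantom, using the ground-truth displacement
(swap in `register_bspline(...).dvf` for the full DIR pipeline):

```python
from bhctvi import (PhantomSpec, generate_phantom, jacobian_map, percentile_map,
                    functional_mask, segment_lungs, define_sections, functional_ratio)

pair = generate_phantom(PhantomSpec(position="supine", grid_shape=(64, 64, 64), seed=101))
lungs = segment_lungs(pair.exhale)
jac = jacobian_map(pair.truth_dvf)
hf = functional_mask(percentile_map(jac, lungs.data > 0), 75.0)
report = functional_ratio(hf, lungs, define_sections(lungs))
print(report[report.lung == "right"][["section", "ratio_pct", "volume_ml"]].to_string(index=False))
print("mean lung Jacobian:", round(float(jac.data[lungs.data > 0].mean()), 3))
```

Output:

```
  section  ratio_pct  volume_ml
   apical  10.396040      3.232
   middle  24.434389      5.304
    basal  30.647709      5.064
diaphragm  35.474006      2.616
mean lung Jacobian: 1.299
```

The highly functional fraction of the right lung grows from ~10% at the
apical level to ~35% at the diaphragm level, and the mean lung Jacobian
(1.299) recovers the phantom's tidal volume ratio of 1.30 — the expected
diaphragm-dominant, gravity-dependent ventilation pattern. Running the full
DIR pipeline (`register_bspline` with the extent-scaled configuration) on
the same phantom classifies 31.3% of the dorsal (dependent) lung half as
highly functional versus 18.7% of the ventral half; a prone phantom
reverses the pattern, and a right-lateral phantom concentrates it in the
right lung. Estimated maps are least reliable in the thin apex/diaphragm
cap sections at this desk scale (see `docs/methods.md`, limitations).

A complete multi-position, multi-subject experiment with CSV reports and
Wilcoxon position comparisons is one call (or `ctvi run` on the command
line):

```python
from bhctvi import RunConfig, run_pipeline
run_pipeline(RunConfig(n_subjects=5, out_dir="ctvi_run", seed=1))
```

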