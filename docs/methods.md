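# Methods

This note documents the models, parameters, numerical choices and known
limitations of `bhctvi`. It is the package's own account of its science;
every empirical statement here is reproduced by the test suite.

## 1. The ventilation model

Breath-hold CT ventilation imaging treats tidal breathing as a deformation
of the expiration-phase anatomy. With **u**(x) the displacement of the
tissue element at expiration position x to its inspiration position, the
local volume-change factor is the Jacobian determinant

V(x) = det(I + ∇u(x)),

computed here with central differences in the grid interior, one-sided
differences at the boundary faces, and each derivative divided by the
physical spacing of its axis, so V is dimensionless on anisotropic grids.
On the zero field V is exactly 1 everywhere (no expansion, no contraction).

Ventilation maps are displayed and analysed as percentiles of V within the
reference population of *all voxels of both lungs combined*; a voxel is
*highly functional* when its percentile rank is ≥ 75. Ranks use the
mid-rank convention, rank = 100·(#smaller + ½·#ties)/N, which is
deterministic, symmetric, and makes a constant map rank 50 everywhere (so
a degenerate map flags nothing at threshold 75). Using the combined-lungs
population rather than per-section populations is deliberate: per-section
percentiles would force every section toward a 25% highly functional
fraction and erase the regional signal the section report is meant to show.

## 2. The synthetic breathing thorax

No volunteer scans ship with this package; a phantom generates paired
exhale/inhale volumes with exact ground truth.

**Geometry.** A body ellipsoid (soft tissue, +40 HU) containing two lung
ellipsoids (−780 HU) and a dorsal spine cylinder (+700 HU) in ambient air
(−1000 HU). Default semi-axes scale with the grid: at the default 96³ grid
with 2 mm isotropic voxels (192 mm extent — a roughly half-scale thorax),
the body is (86, 72, 90) mm and each lung (22, 30, 40) mm, centred ±28 mm
off the mid-sagittal plane. Patient axes are fixed: x right→left,
y anterior→posterior, z inferior→superior; gravity points +y in supine,
−y in prone, −x in right lateral decubitus, +x in left lateral decubitus.

**Ground-truth deformation.** The field is assembled from single-coordinate
building blocks in a triangular dependency pattern — u_x(x, y), u_y(y),
u_z(x, y, z) — so det(I + ∇u) is exactly the product of the three diagonal
strains wherever the boundary envelope is inactive. Inside the lungs the
Jacobian has the closed form

J = (1 + k)² (1 + k_z) · m(s) · m_c(z),

with transverse strain k, cranio-caudal strain k_z = 2k, a linear gravity
modulation m(s) = 1 + γ(s − s₀) spanning `gravity_gradient` (default 0.30)
across the lung extent along gravity s, and a diaphragm-ward modulation
m_c(z) spanning 0.25·`gravity_gradient` from apex to base. Both modulations
vanish when `gravity_gradient` = 0, leaving a spatially constant lung
Jacobian. The base strain k is calibrated by a scalar root-find so the mean
lung Jacobian equals `global_expansion` (default 1.30, a typical tidal
total-lung volume ratio); because the modulations are linear, their lung
averages are exactly their values at the lung centroids, making the
calibration closed-form and bit-reproducible.

**Position-specific motion.** The same Jacobian field is carried by
different displacement mechanisms per position, following the positional
physiology the pipeline is meant to detect:

* *supine and lateral decubitus* — an anti-gravity displacement q(s) along
  −ĝ whose derivative realises m(s); in supine, q is anchored at the
  dorsal (dependent) edge so all motion is dorsal→ventral, opposing
  gravity; lateral positions split the anchor symmetrically.
* *prone* — motion stays parallel to the ground: m(s) is split between a
  lateral (x) stretch (exponent 0.25) and the cranio-caudal stretch
  (exponent 0.75), so the prone field is diaphragm-dominant with
  essentially no displacement along gravity.

Because supine and prone share the Jacobian form, mirroring the supine
phantom's gravity axis reproduces the prone ground-truth Jacobian *inside
the lungs* voxel-exactly (the displacement fields themselves are
intentionally not mirror images). The cranio-caudal stretch is anchored at
the lung z-centre (both the apex region and the diaphragm region displace);
confinement tapers (smooth lung-footprint weights, linear ramps, and a C¹
body-radius envelope that zeroes the field outside the body) bring every
component to rest before the skin. The generator rejects any configuration
whose discrete ground-truth Jacobian drops to ≤ 0.01 anywhere in the body
(a folding deformation); the default conditions and the cohort jitter range
were verified to stay clear of this guard.

**Intensities.** Both phases are rendered from the same continuous
functions: partial-volume interfaces (smooth edge profiles ~4 mm wide,
emulating the scanner point-spread function), a two-scale Gaussian random
parenchymal texture (SD 40 HU at correlation lengths 8 and 20 mm, stored as
cubic-spline coefficients so neither phase is rendered sharper than the
other — a stand-in for the vascular/parenchymal structure that
intensity-based DIR needs), gas-density rescaling of air-like voxels
HU' = −1000 + (HU + 1000)/J (expansion dilutes parenchymal density; soft
tissue and bone are carried rigidly), and independent additive Gaussian HU
noise (SD 20) per phase. The inhale volume is rendered through the exact
inverse deformation (fixed-point iteration on the analytic field), so the
ground-truth field maps inhale back onto exhale to interpolation accuracy.
All randomness flows from a single integer seed; identical specs give
bit-identical phantoms.

## 3. Registration

A multi-resolution cubic B-spline free-form deformation, written directly
on a control lattice aligned with the voxel grid:

u(x) = Σ_j c_j β³((x − x_j)/h).

Dense-field evaluation and its exact adjoint are separable convolutions, so
the metric gradient is analytic; the derivative of the trilinearly
interpolated moving image is sampled exactly (cell-wise forward
differences), and out-of-domain samples blend continuously toward ambient
air. Each pyramid level adds a residual deformation on top of the field
accumulated so far and minimises

E(c) = metric + λ · Σ (Δ²c / h²)² h³

by L-BFGS-B. The penalty is the squared second difference of the control
coefficients scaled to physical curvature and integrated over knot cells,
which makes λ comparable across levels: coarse smooth deformations are
cheap while voxel-scale wiggles on a fine lattice are expensive. Everything
is deterministic — dense metric, quasi-Newton optimiser, no sampling — so
registration needs no seed and reruns are bit-identical.

Metrics: `ssd` (mean squared HU difference; the default for mono-modal
CT–CT), `ncc` (one minus global normalised cross-correlation), and `sstvd`
(tissue-volume-preserving SSD, comparing (HU+1000)·J against the fixed
image's HU+1000 — the natural metric under gas-density rescaling). SSD
remains the default: in experiments the explicit Jacobian factor of `sstvd`
absorbs intensity differences without moving tissue, degrading the
recovered field. An optional region-of-interest mask restricts the metric
(lung-masked DIR); an optional initial field supports staged registration.

Default schedule: two levels, image shrink factors 4 and 2 with Gaussian
smoothing (σ 2 and 1 voxels), knot spacing and curvature weight scaled to
the phantom extent — 48/32 mm and λ = 1.0 at 192 mm extent, 32/16 mm and
λ = 0.3 at 128 mm (`registration_config_for_extent`). The coarse-to-fine
knot spacings track the lung size (the finest lattice resolves within-lung
gradients at roughly half a lung diameter); finer lattices were found to
trade rank fidelity of the Jacobian for noise chasing. The estimated field
is rejected if its Jacobian drops to ≤ 0.05 (folding guard).

## 4. Anatomy, sections and statistics

Lungs are segmented by thresholding HU < −400, discarding components that
touch the grid border (ambient air), keeping the two largest components and
assigning left/right by centroid (a fused component is split at the
mid-sagittal plane). Volumes are voxel counts × voxel volume.

The four analysis sections are axial slabs (default 3 slices) centred at
fractional cranio-caudal positions 0.15, 0.40, 0.65, 0.88 of the lung
extent, counted from the apex — a landmark-free surrogate for the aortic
arch / carina / heart / diaphragm levels used on real CT, since ellipsoid
phantoms have no such landmarks. Slab thickness 1 restores a literal
single-slice reading. Ratios divide highly functional voxels by the
section∩lung voxel count; an empty intersection yields NaN (flagged), not
zero.

Displacement orientation per region: gravity alignment Σ(u·ĝ)/Σ|u|
(magnitude-weighted mean cosine; −1 = motion opposing gravity) and ground
parallelism mean √(1 − (û·ĝ)²) ∈ [0, 1], both over voxels with |u| above a
0.5 mm floor (near-zero vectors carry no orientation information; if all
are below the floor the statistics are undefined and flagged).

Position contrasts use the two-sided Wilcoxon signed-rank test with zero
differences dropped and mid-ranks for ties. P-values are exact for n ≤ 25:
the distribution of the signed-rank sum under random sign assignment is
accumulated by dynamic programming over doubled (integer) ranks, which
equals full 2ⁿ enumeration — verified against a brute-force oracle up to
the cohort size of 13 — while remaining O(n·Σr). Beyond n = 25 a normal
approximation with tie-absorbing variance Σr² and continuity correction is
used. The per-comparison threshold is α/m with m = 3 position contrasts;
0.05/3 is displayed truncated to "0.016".

## 5. The pipeline

`run_pipeline` simulates n subjects × positions: subject-jittered phantoms
(expansion SD 0.015, gradient SD 0.01, clipped at 2 SD — within the
generator's folding-validated envelope), registration (or the ground-truth
field in `registration_mode="truth"`, which exercises the analysis chain
quickly), ventilation maps, segmentation, section reports, vector
summaries, and — with ≥ 2 subjects — Wilcoxon position comparisons. Each
run directory records the exact configuration, per-stage wall times and the
package version; identical configurations reproduce identical CSVs.

## 6. What the phantom does and does not show

Passing tests on the phantom demonstrate that the pipeline's mathematics is
correct (exact anchors, volume conservation, classification counts, test
exactness) and that the end-to-end DIR pipeline recovers the *qualitative*
positional physiology: dependent-side concentration of highly functional
lung in supine/prone/lateral positions, monotone growth of section ratios
toward the diaphragm, dorsal→ventral supine motion and ground-parallel
prone motion. They do not demonstrate quantitative accuracy on clinical
scans: the phantom has no airways, vasculature trees, cardiac motion,
pleural sliding or scanner physics, its texture is a Gaussian surrogate,
and its half-anatomical scale roughly doubles strains relative to real
tidal breathing.

Known quantitative limits at the default desk scale, measured against the
analytic ground truth on the 96³ supine phantom: mean endpoint error of the
registered field inside the lungs ≈ 1.3 mm (≈ 0.67 voxel) with a Spearman
rank correlation ≈ 0.6 between estimated and true Jacobians. The error is
dominated by a noise-independent smooth component where the deformation
transitions sharply just outside the lungs, plus medium-scale fluctuations
whose strain errors are comparable to the gravity-modulation signal itself;
half-fraction and section-level statistics average over these fluctuations,
which is why the positional patterns are recovered robustly while
voxel-level rank fidelity is limited. Estimated maps are least reliable in
the thin apex and diaphragm cap regions.

Other deliberate simplifications: a single tissue class for the chest wall
and abdomen; sections defined by fractions rather than anatomical
landmarks; lobar ("each lung lobe") vector summaries approximated by whole
lungs and cranio-caudal sections, since the phantom has no lobes.
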