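# Methods

`vox3dmsi` reconstructs serial-section MALDI mass spectrometry imaging
(MSI) data of micron-scale 3D cell cultures into voxel volumes and
analyses them at the level of 3D objects rather than 2D pixels.  This
note documents the models, the parameters that matter, the synthetic
phantom that stands in for instrument data, the numerical choices, and
the known limits of the approach.

## Data model

A *section* is one centroid imzML file: a peak list per pixel on a 2D
raster (20 × 20 µm² for spheroids, 10 × 10 µm² for organoids), cut at a
section thickness of 20 µm.  On read, every centroid peak is snapped to
the nearest entry of a shared m/z feature axis within a ppm tolerance
(default 10 ppm, matching the usual annotation tolerance; peaks that
snap to the same entry are summed so ion counts are conserved).  A
z-ordered list of sections with a common axis forms a dataset; z order
comes from an explicit sample-sheet manifest, never from file names.
A *voxel* combines the in-plane raster with the section thickness; at
the standard raster one voxel is 20 × 20 × 20 µm³ = 8000 µm³.

## Reconstruction

Sections are aligned with in-plane rigid transforms (rotation about the
image center, then translation).  Registration is driven by a single
morphology-defining landmark ion image after per-pixel RMS
normalization (each spectrum divided by its root-mean-square, removing
per-pixel total-signal variation).  The similarity metric is normalized
cross-correlation (NCC), optimized by a three-level multi-resolution
regular-step gradient descent (SimpleITK backend, at most `max_iters`
iterations per level, default 400), with linear resampling and
out-of-frame treated as empty.

Two registration refinements proved necessary on round samples:

* **Rotation multi-start.**  Spheroid cross-sections are nearly
  circular, so the NCC objective is shallow and multi-modal in the
  rotation angle.  The descent is restarted from several initial angles
  (0°, ±6°, ±12°) plus one translation-only search with the rotation
  locked.
* **Interior re-scoring with a smallest-rotation tie-break.**
  Candidates are compared by NCC over the eroded interior of the fixed
  foreground.  Two reasons: resampling a rotated image blurs it, and at
  the sharp tissue/background rim (RMS normalization re-sharpens that
  rim) the blur alone can raise whole-frame NCC, favouring spurious
  rotations; and on sections whose interior is too small to carry
  angular information the rotation is genuinely undetermined, in which
  case the smallest rotation within a small score margin is kept.

Stacking uses slice 0 as the reference and registers each slice to its
already-transformed predecessor (`reference="chain"`); a
middle-reference mode exists to halve drift accumulation.  The
recovered transform is applied to every feature channel (linear
interpolation) and to the foreground mask (nearest neighbour).

Reconstruction quality is reported as the product-moment correlation of
the landmark channel between adjacent slices, computed over the union
of the two foreground masks so that misalignment is penalized; the
before/after comparison of this quantity is the standard QC view.

### What rigid chain registration can and cannot recover

Registering consecutive *different* sections is limited by how much the
content genuinely changes from section to section, not only by noise.
On phantoms whose aligned adjacent-slice correlation matches the values
typical of real landmark ions (≈ 0.9), the *global* NCC optimum for a
pair sits 1–4° away from the true alignment even with zero measurement
noise — no optimizer can do better than the metric's own optimum — and
chain stacking composes these per-pair biases into a random walk.
Pole sections (small, nearly circular) carry no rotation information at
all.  Consequently the composed per-slice transform should not be
expected to match the planted perturbation to sub-pixel/sub-degree
precision over a 30-section chain; what registration reliably delivers
is the large gain in adjacent-slice correlation, i.e. a coherent
volume.  The validation suite measures both quantities and reports
them honestly.

## Segmentation

Feature selection follows the usual untargeted workflow: a sliding
window local-maximum filter on the dataset mean spectrum with an
absolute intensity threshold, then ROC-based selection of features
discriminating two pixel groups (per-feature AUC from midrank
statistics; score `max(AUC, 1−AUC)`, default threshold 0.65).
"Weak de-noising" is a 3×3 median filter restricted to foreground
pixels (reduced neighbourhood at edges).

Spatial segmentation is bisecting k-means under correlation distance
(1 − centered cosine similarity): the leaf with the largest
within-cluster summed distance is repeatedly split by 2-means with 10
seeded restarts until the requested leaf count is reached.  The split
is computed on row-standardized vectors (centered, unit norm), with the
2-means centroid re-standardized after every update; the procedure is
deterministic for a fixed seed.  Zero-variance members cannot carry
correlation structure; they are held out, assigned to the nearest leaf
by Euclidean distance at the end, and reported.  Leaves are mapped to
named regions either by an explicit leaf→region map or by
marker-guided auto-assignment (lowest-total-intensity leaves become
background; other leaves take the region whose marker channel is
relatively strongest in their centroid), keeping the pipeline
scriptable while supporting the conventional manual choice.

## Voxel objects

A region mask volume is decomposed into 3D connected components
(default 26-connectivity, configurable to 6/18; the more permissive
default matches visually contiguous clusters).  Components are labeled
in decreasing voxel count and classified as V1 (< 10 vx), V2 (10–100
vx, boundaries inclusive) or V3 (> 100 vx).  V1 objects sit at or
below the resolving power of a 20 µm raster and are flagged as likely
noise but retained in all outputs; excluding them is a statistics-stage
choice.  Geometry is exact voxel-face accounting: volume = count ×
voxel volume; surface area = exposed faces × face area, with
anisotropic voxels supported (in-plane faces have area
pixel × thickness).  Shape fidelity of this rasterization is validated
against voxelated analytic spheres (voxel-center inclusion rule): at a
radius of 15 voxels the voxelated volume is within 5% of (4/3)πr³ and
the surface/volume error decreases monotonically with radius.

## Differential statistics

The unit of replication is the 3D object, never the voxel — testing on
voxels would pseudo-replicate by two orders of magnitude.  Per object,
the mean intensity over member voxels forms its profile.  Between two
object groups the package computes a two-sided t-test per feature
(Welch's unequal-variance form by default; Student's variant available),
Benjamini–Hochberg adjustment across the analysis feature list, and the
log2 fold change of group means with a small additive offset (smallest
positive group mean × 10⁻³) guarding zeros.  A feature is significant
when the adjusted p is below alpha and |log2 FC| exceeds the threshold
(defaults 0.01 and 1, the spheroid workflow; the organoid comparison
conventionally uses 0.05 and 1.75).  The 2D marker workflow uses
Cohen's d (pooled-sd, n−1) per feature and calls a marker concordant
when |d| ≥ 0.8 with equal sign in both the within-biculture and
between-monoculture comparisons.

## The phantom

Because no public instrument dataset accompanies this workflow, every
stage is validated on synthetic phantoms with complete ground truth.

**Geometry.**  Biculture mode: a 600 µm diameter spheroid (30 sections
at 20 µm) of "cancer" tissue with 14 embedded non-overlapping
"fibroblast" cluster spheres, stratified over the three size classes
(2 V1 / 6 V2 / 6 V3 by default) with at least two voxels of cancer
between clusters so 26-connectivity cannot merge them.  Organoid mode:
a hollow shell with an off-center lumen (offset 15% of the radius so
the cross-sections are not concentric).  Voxelization uses the
voxel-center rule for the truth labels.

**Intensities.**  Per-feature region means define a marker panel: a
landmark channel high across all tissue with cancer/fibroblast
contrast, four markers per region, three planted effect carriers
(log2 FC +2, +2, −2 between V2 and V3 fibroblast objects), a weak
two-channel embedding-matrix signature in the background, and null
channels.  Three realism terms are applied:

* *Partial volume*: solid boundaries are rendered with a one-pixel
  linear coverage ramp, because a 20 µm MALDI pixel averages over its
  footprint.  Interior voxels still equal their region mean exactly;
  the binary model is available (`edge_width_px=0`).
* *Landmark texture*: a smooth multiplicative log-Gaussian field
  (amplitude 0.5; correlation lengths 8 voxels along z, 2.5 in-plane)
  on the landmark channel.  Without internal angular structure a
  spherical phantom is rotationally symmetric and rotation recovery
  would be meaningless.  The z-correlation length was chosen so the
  aligned adjacent-slice landmark correlation (≈ 0.85–0.93) matches
  what landmark ions typically show in real serial-section data.
* *Noise*: per-voxel-per-feature multiplicative lognormal (σ = 0.15)
  plus additive Gaussian (σ = 2 a.u. against tissue means of 20–100),
  truncated at zero.  MSI intensities are positive and
  heteroskedastic, hence the multiplicative-dominant model; the
  instrument literature does not pin these numbers, so they are
  package choices exposed in the spec.

Each section is finally perturbed by an independent random rigid
transform (uniform within ±5 px and ±10°), recorded in the truth.
Perturbations are per-section, not cumulative, because sectioning and
mounting errors are per-slice; a drift mode is not needed for the
standard checks.

**What the phantom does not emulate.**  Mass spectra themselves
(isotopes, adducts, peak shape), matrix application artifacts, elastic
tissue deformation, section tearing/folding, and chemical identity.
Passing phantom tests therefore demonstrates the correctness and
calibration of the computational chain, not robustness to every
artifact of real sample preparation.

## Validation experiments and problem sizes

The `validation` module (run by `scripts/acceptance.py` and the
acceptance test suite) uses these scales, chosen to exercise each claim
at meaningful statistical resolution:

* transform recovery: 20 full-size phantoms (30 sections each);
* QC correlation gain: 100 scaled phantoms (300 µm spheroid,
  14 sections) so that 100 full stack-register-correlate cycles remain
  tractable;
* object-picking oracle: 100 random 20³ masks at density 0.2 against a
  hand-written breadth-first flood fill;
* statistics calibration: 1000 random p-vectors against a brute-force
  BH step-up construction, 2000 Gaussian-null Welch replicates
  (n = 20/20), 200 power replicates with a planted |log2 FC| = 1.5 at
  15% object-level noise among 99 null features;
* end-to-end: one default biculture phantom through
  reconstruct → segment → object picking → volcano.

## Known limitations

* Rigid in-plane registration only; elastic deformation is an
  extension point, not implemented.
* Composed transform recovery over long chains is content-limited (see
  above); the package reports honest recovery rates rather than
  claiming sub-degree chain accuracy.
* Correlation-distance clustering is scale-invariant by design; region
  separation therefore relies on spectral *shape* contrast, and
  background separation relies on the off-tissue matrix signature.
* The ROC feature selector assumes two groups; multi-class selection
  is out of scope.
* Object statistics assume objects are independent replicates; spatial
  dependence between neighbouring objects within one spheroid is not
  modelled.
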