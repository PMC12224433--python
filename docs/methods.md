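# Methods

`cordmorph` measures the shape of the spinal cord on axial slices of a
binary segmentation, brings those per-slice measures into the slice
coordinates of the PAM50 spinal cord template without warping any image,
and aggregates many subjects into a normative database against which an
individual can be Z-scored. This note describes the underlying model,
the choices that were genuinely open, and what the synthetic generators do
and do not emulate.

## Per-slice morphometry

All volumes are reoriented to RAS+ on load; axial slice `z` is
`voxels[:, :, z]`, with `z` increasing toward superior. Six measures are
computed per slice:

* **CSA** (mm²) — positive-pixel count × in-plane pixel area, multiplied
  by `cos(θ)` where `θ` is the angle between the cord centerline tangent
  and the superior–inferior axis. The cord crosses axial planes obliquely
  (typically up to ~30° in the lower cervical spine), and an oblique cut
  through a tube overestimates its true cross-section by `1/cos(θ)`; the
  multiplication is the first-order correction.
* **AP and transverse diameters** (mm) — support widths of the
  *equivalent ellipse* (the ellipse sharing the pixel set's second-order
  central moments) along the anteroposterior and right–left axes:
  `4·sqrt(S_uu)` for moment matrix `S` in mm². The AP extent is corrected
  by `cos(θ_sag)` and the RL extent by `cos(θ_cor)`, the tangent's tilt
  components in the sagittal and coronal planes, so each diameter is
  corrected only for the obliquity that stretches it.
* **Compression ratio** (a.u.) — AP / transverse diameter, no clipping.
* **Eccentricity** (a.u.) — `sqrt(1 − (b/a)²)` from the equivalent
  ellipse's semi-axes `a ≥ b`; 0 is a circle. Because the moment matrix is
  computed in millimetres, voxel anisotropy is handled naturally.
* **Solidity** (%) — positive-pixel count over the pixel count of the
  convex hull of all positive pixels. Using *all* positive pixels makes
  the measure meaningful when the cord appears as disconnected in-plane
  components (these are kept, with a warning, never dropped).

Moments include the per-axis `w²/12` within-pixel term, so the equivalent
ellipse of a rasterized ellipse reproduces the continuous one to first
order. Slices where shape is undefined — fewer than three pixels, or
collinear pixels — are excluded from the output with a warning.

The centerline is the per-slice intensity centroid smoothed by a
polynomial fit (degree 3 by default, configurable 1–5) of each in-plane
coordinate against the SI coordinate in mm; tangents come from the
analytic derivative, which also gives one-sided tangents at the volume
boundaries. A low-order fit was chosen deliberately: per-slice centroids
of a binary mask carry sub-voxel noise, and differentiating a flexible
curve through them amplifies that noise into spurious angles. The fit
requires at least `degree + 1` nonempty slices.

Diameters are moment-based rather than Feret (caliper) extents: a single
protruding boundary voxel moves a Feret extent by a full voxel but barely
perturbs a second moment, and the moment route is consistent with the
ellipse-based eccentricity definition.

## Normalization to PAM50 slice coordinates

The package deliberately avoids image registration to the template.
Warping a subject's cord into template space distorts the very anatomy
being measured (particularly in injured cords); instead, metrics computed
in native space are *resampled per vertebral level*. For a level with `n`
native slices and `m` template slices, native values sit at the normalized
coordinate `u = i/(n−1)` and the template profile is read off at
`u = j/(m−1)` by linear interpolation, independently per metric and per
level. Endpoints map exactly, so disc-adjacent values land on
disc-adjacent template slices; interpolated values are convex combinations
of that level's native values, and nothing is smoothed across a disc.

Level span convention (identical in native and template space): vertebra
`k` spans `[disc_{k+1}, disc_k − 1]`, where disc `k` is the disc at the
top of vertebra `k` — a level includes its inferior disc slice and stops
below its superior one. The packaged template level map stores boundaries
964 / 939 / 908 / 871 / 834 / 801 / 770 / 736 / 692 for discs 1–9 (disc 1
is the superior C1 boundary, not an anatomical disc) at 0.5 mm slice
spacing; mid-level slices are the range midpoint with ties rounded toward
superior. Under this convention the map reproduces the conventional
landmark slices (C1 → 951, C3/C4 disc → 871, T1 → 714, …). An alternative
loader can rebuild the map from a labeled template segmentation.

Levels not bounded by two labeled discs (field-of-view edges) are
excluded, never extrapolated. A level with a single defined native slice
is constant-extended with a warning; native slices where a metric is
undefined are dropped from that metric's interpolation support.

## Normative database

Per template slice and metric the database stores `n`, mean, SD and
`COV = 100·SD/mean` across subjects. Sample SD (`n−1`) is used throughout,
as is standard when the SD will calibrate Z-scores. Slices with fewer than
`min_n` subjects (default 2) are reported missing. COV is summarized per
slice, averaged per vertebral level, and overall as mean ± sample SD over
all covered slices.

Cohort handling: subjects whose participants-table `pathology` entry is
anything other than empty/healthy are excluded before any aggregation,
and pathology-flagged records can never enter an aggregate regardless of
filtering. Filters compose over sex, manufacturer and age decades
(10–20, 21–30, …, 51–60, upper bound inclusive).

Group differences use the two-sided Wilcoxon rank-sum test per slice at
α = 0.001 with **no** multiple-testing correction — the stringent α is the
only control, and neighbouring slices are strongly correlated so a formal
correction over ~270 slices would be misleadingly conservative.
Demographics report mean ± SD per sex with Shapiro–Wilk normality checks
and rank-sum male-vs-female p-values, with pairwise deletion of missing
values.

Z-scores are `(x − mean)/SD` per slice and metric, undefined (and
flagged) where the database SD is zero.

## Synthetic generators

**Cord phantoms** are tubes of elliptical cross-section rasterized on a
0.8 mm isotropic grid by default (matching typical high-resolution T2w
acquisitions). Semi-axis profiles are piecewise-constant per level so that
the per-slice ground truth stays closed-form: CSA `πab`, diameters `2b`
(AP) and `2a` (RL), compression ratio `b/a`, eccentricity from the
semi-axes, solidity 100%. The default cervical profile takes each level's
semi-axes from the packaged normative mid-level diameters, which
reproduces the physiological bulge at C4–C5. Tilt is implemented as a
shear of the tube axis: the specified ellipse is the *perpendicular*
cross-section, so axial sections are stretched by `1/cos(θ)` — exactly the
effect the angulation correction must undo. In-plane rotation is supported
only at zero tilt (the sheared, rotated tube would no longer have a
closed-form axial section).

A voxel is inside if its center satisfies the ellipse inequality. Binary
rasterization of a fixed ellipse at 0.8 mm carries an alignment-dependent
area error of a few percent (up to ~8% for the smallest, T1-sized
sections) whose sign depends on where the boundary falls between voxel
centers and whose mean over alignments is near zero. The generator
therefore dithers the construction center sub-voxel per slice with a
deterministic low-discrepancy sequence, so consecutive slices sample
different alignments and the discretization error averages out along a
level. Accordingly, the oracle comparisons are made per level (level-mean
measured vs closed form, which agree to a few tenths of a percent), with
per-slice deviations bounded by the documented discretization envelope.
The ground-truth centerline tracks the dither, and a fixed spec is
bit-reproducible (jitter, when enabled, is seeded).

**Synthetic cohorts** emulate the released per-subject template-space
CSVs. Per-slice metric values are drawn from normal distributions whose
mean/SD profiles are linear interpolations of the packaged normative
landmark tables (separate male and female profiles by default; a pooled
variant removes the sex effect). Each subject carries a per-metric random
intercept with ICC 0.8: value = `μ(s) + σ(s)·(√0.8·u + √0.2·ε_s)`, keeping
the marginal per-slice SD at `σ(s)`. The intercept reflects that a
subject's cord is uniformly large or small — neighbouring-slice
correlations in real morphometric profiles are high — and it is what makes
"no slice significant" a meaningful null outcome across ~270 correlated
tests; an independent-slice generator would produce ~0.24 false-positive
slices per null cohort run. Demographics default to the source-study
composition: 203 healthy subjects (105 M / 98 F), vendors
Siemens/Philips/GE at 139/36/28, age ~N(28.7, 5.6²) truncated to 19–52
years (truncation shrinks the realized SD slightly), heights and weights
per sex, and optionally 64 pathology-flagged subjects that any normative
aggregate must reject.

What the generators do **not** emulate: MRI intensities or segmentation
errors beyond boundary jitter, cross-metric correlations within a subject
(intercepts are independent per metric), smooth within-level profile
variation (phantom profiles are piecewise-constant), and age or vendor
effects on the metrics unless explicitly configured. Passing tests
demonstrate the correctness of the measurement, interpolation and
aggregation machinery under known truth — not the biological fidelity of
any particular normative value.

## Statistical behaviour of the per-slice sex comparison

With the packaged tables' male–female CSA gap (≈2.6–5.8 mm² depending on
level) and per-slice SDs (≈5.6–9.9 mm²) at n = 105/98, the per-slice
rank-sum test at α = 0.001 has a normal-approximation power ranging from
~0.3 (C6–C7, C7–T1) to ~1.0 (C1–C2); simulation with the default
generator detects the gap on roughly half to two-thirds of slices per
cohort draw, with large between-draw spread induced by the shared subject
intercepts. Null (pooled-profile) cohorts flag no slice in the large
majority of runs. Both rates are recomputed, not asserted, by
`scripts/acceptance.py`.

## Problem sizes and numerical choices

Default analyses operate on the full covered template span (272 slices,
C1–T1). Phantom validation uses the cervical phantom at 0.8 mm
(~176 slices, in-plane grids of ~25×19 voxels); simulation-based checks
use cohorts of n = 203 with 5–20 seeded repetitions. Ties in the
mid-level slice round toward superior. Masks are binarized at > 0.5 on
load. Degenerate inputs fail loudly: empty volumes, sub-voxel phantom
semi-axes, non-monotone disc labels, fewer than two subjects after
filtering, and zero-SD slices in Z-scoring are all explicit errors or
flagged missing values rather than silent results.

## Known limitations

* The angle correction is first-order; at extreme angulation (> ~40°) a
  cosine scaling of in-plane measures no longer approximates the true
  oblique section well.
* Equivalent-ellipse diameters understate caliper extents for strongly
  non-elliptical sections; this is intentional (robustness) but means
  "diameter" should be read as a moment-based, not maximal, extent.
* The normalization assumes disc labels are reliable; it inherits any
  labeling error directly, shifting a whole level's worth of slices.
* Normative aggregates are only as representative as the cohort behind
  them; the packaged landmark tables derive from a young, predominantly
  single-vendor population.
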