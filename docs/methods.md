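# Methods

This note documents the conventions, models and design choices behind
`dirqa`, in the spirit of a physics commissioning report: every knob that
could change a number is named here, and every convention is echoed into
the run manifest of each report.

## Geometry model

All computations happen on axis-aligned voxel grids in patient millimetre
coordinates, axis order (x, y, z), with anisotropic spacing (the default
phantom uses 2 mm in-plane and 2.5 mm slices, matching typical
head-and-neck planning CTs). Oblique DICOM geometry is rejected with an
explicit error rather than silently resampled: the agreement metrics are
defined on a common grid, and hidden resampling would contaminate them.

Contours are voxelized by the even-odd rule at voxel centers: a voxel is
foreground iff its center lies inside an odd number of that slice's
polygons, so concentric contours carve holes. Polygons are assigned to the
nearest grid slice (ties broken toward the lower index) because RTSTRUCT z
values rarely land exactly on slice centers; a polygon farther than half a
slice spacing from every slice is an error, not a silent drop.

## Geometric agreement metrics

**DSC** is computed from voxel counts. If exactly one mask is empty the
DSC is 0 — a real failure mode (a nodal target visible only on the
re-planning CT cannot be recreated by propagation from the initial CT) that
must stay in the statistics. If both masks are empty the value is marked
not evaluable (NaN) and excluded from medians with an explicit exclusion
count. Qualitative agreement bands follow the kappa-style scale quoted to
two decimals; values are rounded half-up to two decimals before banding
(decimal, not binary, rounding, so 0.205 banding as 0.21 → "fair" is
stable).

**Surfaces** are the centers of voxel faces shared by a foreground and a
background voxel. Face centers (rather than voxel centers or a marching
cubes mesh) make sDSC at τ = 0 meaningful when two masks coincide on the
same grid: coinciding masks share every surface element exactly. The
τ = 0 tolerance is 1e-6 mm; sDSC_0mm is inherently grid-dependent and is
reported as such. The sDSC denominator is the total surface-element
*count* |S_RO| + |S_DIR|; area weighting of anisotropic faces is a
possible variant but counts are the default convention here.

**Distances** between surfaces use a KD-tree; a deliberately naive
O(n·m) pairwise implementation is kept in the package
(`pairwise_min_distances_bruteforce`) as the validation oracle, and the
test suite requires agreement to 1e-6 mm on hundreds of random mask pairs.

**HD95 dialect.** Percentile-of-Hausdorff definitions differ between
tools. `dirqa` computes the linear-interpolation 95th percentile of each
directed distance multiset and reports the maximum of the two directions —
symmetric, and the most common convention in segmentation QA. The plain
HD (max of directed maxima) is also available. The dialect string is
written into every manifest.

## Dosimetric metrics

Dose is sampled by trilinear interpolation at the foreground voxel centers
of the evaluated structure; both plans' dose grids are interpolated to the
*structure's* grid, never the reverse, because the physician structure
defines the evaluation domain Ω. Voxels outside a dose grid's support are
excluded and counted.

DVH point metrics use sorted samples with linear-interpolation percentiles
(no dose binning): D95% and D50% are the 5th and 50th percentiles of the
per-voxel doses, Dmax is the maximum sampled voxel dose (no near-max
volume qualifier such as D0.035cc). V95% is the fraction of samples at or
above 0.95 × prescription; a structure passes coverage at V95% ≥ 0.95.

The spatial dose-difference pass rate DD_τ uses |Δ(x)| ≤ τ with
Δ(x) = (D_DIR − D_RO)/D_RO. The absolute value is deliberate: a signed
criterion Δ(x) ≤ τ would trivially pass every cold spot; the signed
variant remains available behind a flag for sensitivity analyses. Voxels
with reference dose below a low-dose guard (default 0.5 Gy) are excluded
from Δ for division stability — inside target volumes this excludes
essentially nothing, and the exclusion count is always reported.

## Statistics

Group comparisons use the two-sided Mann–Whitney U test at α = 0.05. When
both samples have n ≤ 8 the null distribution of U is enumerated over all
C(n+m, n) assignments of the pooled values — this enumeration handles ties
correctly (identical samples give p = 1 exactly), which off-the-shelf
exact implementations typically do not. Larger samples use the normal
approximation with tie and continuity corrections (scipy).

Pearson correlations (metric vs. per-structure volume change) report the
t-transform p-value and a Fisher-z 95% confidence interval (degenerate at
n = 3 or |r| = 1, where the CI is the full interval).

Structures from one patient are treated as independent observations — the
convention of small DIR-commissioning cohorts — and every report carries a
footer flagging this clustering rather than modelling it. No
multiple-testing correction is applied. Outliers are never removed:
values beyond 1.5×IQR are annotated in the summaries and kept (a huge HD95
from new nodal disease is a finding, not noise).

## Synthetic phantom

The generator emulates the statistical structure of a paired
planning/re-planning head-and-neck cohort with fully known ground truth:

- **Structures**: an ellipsoidal primary GTV (semi-axes ≈ 11/9/8 mm) and
  1–3 spherical nodal GTVs (≈ 6 mm), CTVs by 5 mm margin expansion, PTVs
  by a further 3 mm expansion (the clinical CTV→PTV margin).
- **Anatomy change** (initial → re-planning): a uniform translation plus
  Gaussian displacement bumps — a radial bump on the primary
  (growth/shrinkage) and a directional bump near the nodes (positioning).
  Cohort draws use radial amplitudes of roughly ±0.8 mm, which on ~10 mm
  structures produce per-structure volume changes spanning about ±25%,
  bracketing the −17%…+15% range typical of re-planned head-and-neck
  patients; the mix of shrinkage, growth and positioning cases arises from
  the sign of the draw.
- **DIR error**: the re-planning masks are warped by a systematic shift
  (≈ 1 mm, random direction per case) plus a smooth random displacement
  field of amplitude ε (default 2 mm, correlation length 12 mm). This is a
  generic smooth-displacement surrogate: it is controllable and
  reproducible, but no claim is made that it matches any particular
  registration algorithm's error structure.
- **Dose**: each dose level contributes its prescription inside its PTV
  and a Gaussian penumbra exp(−d²/2σ²) of the distance outside it
  (σ = 5 mm, a typical high-gradient falloff scale); the voxel dose is the
  maximum over levels, giving a simultaneous-integrated-boost-like pattern
  with tiers from {54, 56, 60, 63, 70} Gy (70 Gy on the tumor chain,
  rotating nodal tiers).
- **Optimizer noise**: replicate plans multiply the dose by (1 + η) with η
  a smooth zero-mean random field of amplitude 2% and 20 mm correlation
  length; 5 replicates per case feed the 10-pairwise-comparison
  reproducibility design.

Random fields are seeded white noise convolved with a Gaussian kernel of
the stated correlation length under periodic boundary handling (which
keeps the field statistically homogeneous — reflective or
nearest-replication filtering inflates the variance near corners and would
distort the max-normalization), mean-removed, and normalized so the stated
amplitude is the field's maximum. All randomness flows from one integer
seed through `numpy.random.SeedSequence` spawning: same seed, same cohort,
byte for byte.

Mask warping is indicator pull-back with linear interpolation and a 0.5
threshold. Nearest-neighbor warping was rejected because its
stair-casing confounds surface metrics at small ε. A consequence of
thresholded warping is a quantization floor: displacements well below half
a voxel pitch can leave a mask unchanged, so degradation-vs-ε experiments
use ε at or above the voxel scale. The forward displacement of any
foreground voxel leaving the grid is an error, not a silent clip.

**What the phantom does not emulate**: CT intensity texture, realistic
beam/arc dose gradients, organ-at-risk anatomy, inter-observer contouring
variability, or the error structure of any real DIR algorithm. Passing
tests on the phantom therefore validates the *metrics and pipeline
mechanics* — agreement with brute-force oracles, correct bookkeeping of
failure modes, monotone response to controlled error — not clinical
performance of any registration tool on real patients.

## Volumes and problem sizes

Structure volumes are voxel counts × voxel volume (voxelized masks, not
polygon slab volumes); the convention is recorded in every report. The
default phantom grid is 56×56×28 voxels at (2, 2, 2.5) mm — large enough
that targets plus margins and penumbra fit with room to deform, small
enough that a 10-case cohort with 5 dose replicates per case generates and
analyzes in seconds; the test suite uses 40×40×20 grids for sweep
experiments across many seeds.

## Known limitations

- Margin expansion measures distances to foreground voxel *centers*; this
  carries a half-voxel inward bias relative to the continuous region
  (≈ 2.7% volume deficit for a 3 mm margin on a 10 mm sphere at 1 mm
  voxels). Composing two expansions consequently loses up to one voxel per
  step relative to a single combined expansion (the discrete triangle
  inequality works in that direction).
- sDSC_0mm only makes sense for masks compared on one common grid.
- Only axis-aligned DICOM geometry is supported.
- The statistics treat structures as independent despite patient
  clustering (flagged in reports, by design).
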