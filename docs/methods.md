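# Methods

This note records the models, conventions and design choices behind
`pancradiomics`, in enough detail that a reader can predict the number the
code will print without reading the code.

## Intensity preprocessing

Scans are min–max normalized over the *whole volume* to [0, 1] (the scan,
not the ROI, is the normalization unit, matching how venous-phase CT is
normalized before radiomic analysis). The map is monotone and idempotent; a
constant volume maps to all zeros — a constant carries no texture signal,
and zero is the conventional fixed point. No resampling to isotropic
spacing is performed anywhere; physical spacing enters only the shape
features.

## Subregion partition

The pancreatic head (including the neck), body and tail occupy roughly
40 / 33 / 26–27 % of the gland's volume. Instead of landmark anatomy
(superior mesenteric vessels, duodenal curve), the partition is a
transparent proportional rule:

1. compute the first principal axis of the pancreas mask's voxel
   coordinates **in physical mm** (raw voxel indices would bend the axis
   under anisotropic spacing);
2. orient the axis so the *head* end — identified as the end whose terminal
   10 % of axis slabs has the larger mean cross-sectional voxel count,
   the head being the bulkiest part of the gland; exact ties fall back to
   the patient-right (smaller x) end — sits at low projections;
3. cut the projection-ordered voxels at cumulative fractions 0.40 and
   0.73 (0.27 for the tail absorbs the rounding of the nominal 26 %).

Cut thresholds are order statistics of the projection, so ties (whole slabs
of an axis-aligned mask) stay on one side of a cut and the realized
fractions are exact to within one slab. Tumors are assigned head vs
body/tail by voxel plurality over the partition labels, body and tail
pooled; an exact 50/50 tie resolves to head (the majority class, and a
deterministic, documented choice — how boundary-straddling tumors should be
assigned is genuinely open). A tumor with no overlap is mapped to the
nearest labeled voxel within 10 mm; farther than that it is unassignable.

## Discretization

Texture matrices consume integer grey levels from fixed-bin-*count*,
equal-width binning over the ROI's own [min, max] intensity range (texture
should reflect intra-tumor contrast, not scan-wide dynamic range). Bin
counts are the powers of two 2¹…2⁸; "bin size" is read as a *count*, the
reading consistent with sweeping 2¹…2⁸. The maximum intensity maps to the
top bin, a constant ROI to level 1 throughout. Bin edges are retained on
the level map for audit.

## Texture matrices

Accumulation is 2D in-plane (the four quadrant directions 0/45/90/135°),
summed over axial slices — z-offsets are not part of the parameter
vocabulary (bin, kernel, angle). The one exception is the size-zone matrix,
which is direction-free and uses full 3D 26-connectivity. The *kernel*
k ∈ 1…5 is the maximal neighborhood radius (Chebyshev distance): GLCM
offsets run at distances 1…k along an angle (one matrix per
distance × angle, symmetrized by adding the transpose), GLDM dependence and
NGTDM neighborhoods span radius k. GLDM uses α = 0 (exact-level dependence,
the common default; configurable). Feature definitions follow the standard
IBSI-style formulas; per-angle features are kept as separate grid columns,
with an angle-averaging helper exposed for the conventional rotation-
invariant variants.

Four co-occurrence features — *inverse cluster shade*, *inverse cluster
tendency*, *Gaussian left polar*, *inverse Gaussian left polar* — have no
published formula anywhere we know of, so this package defines them
explicitly: the first two are the cluster shade/tendency moments of the
complement distribution p′(i,j) ∝ max(p) − p(i,j) (undefined, hence NaN,
for a perfectly uniform matrix); the polar pair weights the
lower-triangular (i ≥ j) probability mass by exp(−(i−j)²/2σ²) with
σ = B/4, and by its complement. These are this package's own documented
constructions for otherwise-undefined names.

Family cardinalities are fixed at first-order 15, shape 20, GLCM 20, GLRLM
15, GLSZM 14, GLDM 12, NGTDM 5. Where the standard feature catalogue
offers more (e.g. 16 run-length features), the least-informative normalized
duplicate was dropped to hit the fixed count: GLRLM omits grey-level
non-uniformity *normalized*, GLDM omits grey-level non-uniformity.

Degenerate inputs produce NaN sentinels rather than errors: a single-voxel
ROI has no co-occurrence pairs (matrix flagged degenerate), correlation on
a zero-variance matrix is undefined, NGTDM coarseness on a texture-free ROI
is capped at 10⁶. Sentinels flow into the feature table and are removed at
screening, mirroring the usual filtering of unusable/infinite values.

## First-order and shape features

Percentiles use numpy's `interpolated_inverted_cdf` method — linear
interpolation of the inverted empirical CDF, under which the 25th
percentile of {0.01, …, 1.00} is exactly 0.25. Kurtosis is reported
non-excess (normal ⇒ 3) to avoid a silent 3-offset; variance is the
population variance; entropy uses a 32-bin histogram by default (the
grid's largest bin count during grid extraction). Constant ROIs yield
variance 0 and NaN skewness/kurtosis.

Surface measures come from a marching-cubes mesh at iso-level 0.5 of the
mask after a narrow Gaussian anti-aliasing (σ = 0.7 voxel): meshing the raw
binary grid produces a staircase surface whose area overestimates the true
boundary by several percent (a digital ball's sphericity would read ≈ 0.92
instead of ≈ 0.98). Masks too small to survive smoothing fall back to the
raw binary mesh. Mesh volume uses the divergence theorem; principal-axis
lengths are 4·√eigenvalue of the physical-coordinate covariance; maximum
diameters use convex-hull pairwise distances. 2D features are evaluated on
the largest-area axial slice, with maximum in-plane diameters reported for
all three orthogonal plane orientations. Because tumor sizes in this
problem are conventionally quoted in cm, the equivalent-sphere diameter
(cm) is included as the twentieth shape feature. A single-slice ROI keeps
its slab-based 3D measures but flatness degenerates to NaN.

## The feature grid

Each family sweeps only the axes it genuinely depends on (table in the
README): GLCM over bin × distance × angle, GLRLM over bin × angle, GLSZM
over bin, GLDM and NGTDM over bin × kernel. First-order and shape are
parameter-free and appear once (first-order entropy is binned at the
grid's largest bin count). The full default grid yields 4507 columns; the
column count is a closed-form function of the grid, asserted against
enumeration in the tests. Extraction is deterministic (bit-identical rows
on re-extraction), never aborts a case (family failures become NaN
sentinels), and crops to the ROI bounding box plus the kernel margin for
speed.

## Screening

Columns with any non-finite value or zero variance are dropped first (a
zero-variance column has no defined t statistic); the filter is idempotent.
Each surviving feature gets a two-sided **Welch** t-test — the groups are
unbalanced (58/42) and variance equality is unverifiable, so the
unequal-variance form is the defensible default — flagged significant at
p < α (default 0.05) with *no* multiplicity correction, matching the plain
5 %-threshold screening this mirrors; a Benjamini–Hochberg flag exists but
is off by default. The t statistic is signed head-minus-body/tail; swapping
groups negates t and preserves p. The Manhattan export writes per-feature
−log₁₀ p grouped by family as CSV and a rendered plot.

## Classification

All seven methods are standard scikit-learn estimators behind one
interface; the adaptations the method names leave open are: "K-Means" is
the supervised nearest-class-centroid rule; linear regression is fit on a
0/1 response and thresholded at 0.5; Naïve Bayes is Gaussian per feature;
KNN uses k = 5 with Euclidean distance; the SVM kernel is linear; bagged
trees are a 50-tree forest with no feature subsampling (pure bagging). All
hyperparameters are exposed in `ClassifierSpec`.

Features are z-scored with training-set statistics inside every model; the
test set is transformed with training means/SDs only, so no information
crosses the split. RFE removes the lowest-ranked features per iteration
until ≤ 5 survive, then refits. Ranking: |standardized coefficient| for
SVM/linear regression/LDA, impurity importance for bagged trees, and the
absolute Welch t statistic (a univariate class-separation score) for the
coefficient-free methods (NB, KNN, centroid) — for these the ranking is
static, so elimination reduces to a sort. `step` defaults to 1 feature per
iteration; a fractional step (e.g. 0.2 of the remaining features) is
provided for wide tables, where single-step elimination from thousands of
columns would re-fit the estimator thousands of times for an identical
endpoint; the test suite exercises 4000-column tables with step 0.2.

The positive class is head throughout; a decision score of exactly 0.5
classifies as head (documented, arbitrary). Scores are head-probabilities
in [0, 1] (sigmoid of the SVM margin, clipped prediction for linear
regression, distance ratio for the centroid rule, predict_proba
otherwise). Evaluation reports the predicted × true confusion matrix,
accuracy / sensitivity / specificity as full-precision percentages rounded
half-up for display, a score-threshold-sweep ROC and its trapezoid AUC.
AUC is invariant to strictly monotone score transforms; ROC coordinates
are non-decreasing.

## The phantom generator

What it emulates: a 100-case cohort split 58 head / 42 body-tail; an
elongated, curved, tapering pancreas (radius 14 mm at the head end down to
6 mm at the tail, length ≈ 13 cm) built as a union of balls along a
randomized centerline on a 48 × 96 × 96 grid at (2.5, 2.0, 2.0) mm
spacing; tumors as volume-preserving anisotropic ellipsoids (axis ratios
0.85–1.18) with smooth radial boundary perturbation (±7 %), placed on the
centerline in the head section (t ∈ 0.06–0.20) or the body/tail section
(t ∈ 0.45–0.85); equivalent-sphere diameters drawn uniformly from
2.4–3.1 cm (head) and 5.6–6.1 cm (body/tail), the cm figures read as
diameters — the unit is ambiguous in the source material, and diameter is
the only reading consistent with tumors that fit inside an abdomen.

Intensities: smooth background (0.32 ± correlated noise), gland +0.06,
tumor base 0.30 plus a +0.15 offset for head tumors (hyperintense; darker
than gland for body/tail), plus in-tumor Gaussian-correlated noise with
class-specific correlation length (σ = 2.5 mm head, 5.0 mm body/tail,
amplitude 0.06) — correlated noise is the minimal imaging stand-in for the
cellular-arrangement differences that drive real texture contrasts, which
have no published imaging model. Volumes are quantized to 16 bit and
min–max normalized. The offset and amplitude were chosen once so planted
effects are detectable at n = 100 without being driven by any single
feature; with both a 2× size contrast and an intensity offset the phantom
classes are in fact close to separable, so classifier tests on phantoms
validate the machinery, not the clinical effect size.

The **null cohort** pushes both classes through an identical process:
offset 0, shared diameter range 3.5–4.5 cm, shared texture correlation
length 3.75 mm (the class midpoint), uniform placement anywhere along the
gland (t ∈ 0.10–0.85). Any class difference detected on it is a false
positive. All randomness flows from one mandatory integer seed through a
`SeedSequence` spawn per case; cohorts are bit-deterministic given the
seed.

What the phantoms do **not** model: CT physics (beam hardening, contrast
kinetics, partial volume), duct dilation, peritumoral infiltration,
inter-scanner variability, and — importantly — realistic *overlap* between
the classes. Passing tests on phantoms therefore demonstrate pipeline
correctness and calibration, not expected real-data accuracy.

## Problem sizes used in the tests

The validation suite runs the study-scale experiments end-to-end: one
100-case null cohort (type-I calibration) and a 100-case train / 100-case
test planted pair (effect recovery and classification), each through the
full 4507-column grid; 200 randomized tiny level maps against brute-force
oracles; RFE on 4000-column tables. Unit tests use reduced grids and
six-case cohorts.

A note on the null calibration: the fraction of features flagged at
α = 0.05 on a null cohort has expectation ≈ α (a 40-permutation study on
one null table gives mean 0.043 — the slight deficit is Welch's mild
conservatism on skewed features), but its *variance* is dominated by
inter-feature correlation: the 4507 columns derive from a handful of
random fields per case, so the effective number of independent tests is
orders of magnitude below 4507 and the single-cohort fraction scatters
widely around α (observed SD ≈ 0.06 across permutations). A tolerance
derived from the binomial SD at 4000 independent features is therefore far
too tight for any single-cohort check; the suite's strict
binomial-tolerance assertion documents this honestly rather than widening
the band.

## Known limitations

* 2D in-plane texture accumulation (except GLSZM) by design; no 3D GLCM.
* No wavelet/LoG filtered feature classes, no DICOM series assembly, no
  registration, no automated pancreas segmentation.
* The proportional subregion partition ignores vascular landmarks; it is
  reproducible, not anatomically exact.
* RFE does not cross-validate inside the training set; the cap of five
  features is the only overfitting control, as in the workflow this
  mirrors.
* Feature values are not harmonized across scanners/protocols; apply the
  pipeline within one acquisition protocol.
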