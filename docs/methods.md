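# Methods

This note documents the models, conventions and design choices behind the
package; the README covers usage.

## Problem setting

Eyes with macular edema (from diabetic macular edema or retinal vein
occlusion) treated with intravitreal anti-VEGF injections differ in how
they tolerate extension of the dosing interval from 4 to 8 weeks:
*rebounders* worsen, *non-rebounders* tolerate the extension.  The
pipeline asks whether 3D texture (radiomics) descriptors computed inside
anatomically defined subcompartments of the baseline SD-OCT cube carry
that outcome signal, and which subcompartment carries most of it.

## Compartment model

A macular cube is indexed (slice, depth, A-scan), depth increasing away
from the vitreous.  Layer surfaces (ILM, EZ, RPE) are per-A-scan depth
fields supplied as input, as are binary IRF/SRF fluid masks — layer and
fluid segmentation is upstream of this pipeline, so the SRF-induced
EZ-to-RPE separation is a property of the input surfaces, not re-derived
here.  Four pairwise-disjoint masks are derived:

| mask | definition |
|---|---|
| IRF  | intraretinal fluid, inside [ILM, EZ) |
| SRF  | subretinal fluid, inside [EZ, RPE) |
| RTC1 | [ILM, EZ) tissue minus IRF |
| RTC2 | [EZ, RPE) tissue minus SRF |

Depth bands are half-open so each voxel belongs to exactly one band;
boundary-voxel ownership is a convention the source material leaves
open.  Analysis is restricted to the central slice window — slices 43–85
(1-based, inclusive) of a 128-slice cube, scaled proportionally with
round-half-up at both ends for other slice counts (22–43 at 64 slices,
4–8 at 12).  Fluid-mode slice selection additionally drops window slices
whose fluid masks are empty and signals explicitly (an exception, not a
zero row) when nothing remains.  Because features are aggregated over
masks, the empty-slice rule affects reporting, not aggregate values.

## Feature bank (962 descriptors per compartment)

Per-voxel 3D texture maps from four families are aggregated over each
compartment mask with four first-order statistics — median, variance
(denominator n), skewness and non-excess kurtosis (standardized 3rd/4th
central moments; a constant sample gets skewness = kurtosis = 0, and
n < 2 leaves the higher moments missing).  The aggregation statistic is
folded into the feature name (`Median-Laws_E3S3S3`), and fused tables
prefix the compartment (`IRF/Median-Laws_E3S3S3`).

The published family totals (52 Haralick, 501 Laws, 383 Gabor, 26
CoLlAGe) do not factor cleanly into parameter-grid × statistic products,
so a versioned JSON manifest is the single source of truth: it
enumerates descriptor names per family in a fixed order and truncates to
the published counts.  The grids behind it:

* **Haralick (52 = 13 × 4).**  13 classical co-occurrence statistics
  computed per voxel from a sliding 5³ window; gray levels min–max
  quantized to 32 within the mask; the symmetric GLCM pools the 13
  unique 3D direction classes; windows are clipped to the mask so no
  out-of-retina intensity enters.  13 maps × 4 aggregations.
* **Laws (501 of 608).**  Separable energy maps (5³ windowed mean
  absolute response) over all ordered triplets of {L3,E3,S3} (27) and
  {L5,E5,S5,R5,W5} (125); triplet order maps to (depth, A-scan, slice).
  152 maps × 4 aggregations, truncated at 501.
* **Gabor (383 of 384).**  Magnitude responses of DC-corrected 2D Gabor
  kernels applied within each B-scan plane, 8 orientations × wavelengths
  {3,4,6,8,10,12} voxels × bandwidths {1.0,1.5}.  96 maps × 4,
  truncated at 383.
* **CoLlAGe (26 = 13 × 2).**  Dominant local gradient orientation per
  voxel from the eigen-decomposition of a 5³-windowed structure tensor,
  split into an in-plane angle in [0, π) and a through-plane angle in
  [0, π/2], quantized to 16 bins; the 13 co-occurrence statistics are
  then computed per voxel on each angle volume and aggregated with the
  median only.  Zero-gradient neighborhoods are assigned bin 0 and
  counted in the log.

Boundary policy: separable convolutions and the Laws energy window use
reflect padding; Gabor slices are symmetric-padded by the kernel
half-size before FFT convolution (so zero-sum kernels annihilate
constants up to the border); co-occurrence windows are clipped to the
volume and mask.  An empty compartment (an eye without SRF is common)
yields 962 missing values, logged, never dropped; imputation happens
only inside cross-validation folds, from fold-train means.

Feature tables are z-normalized per column to mean 0, population-sd 1;
zero-variance columns become 0 and are flagged.  Fusions concatenate
prefixed compartment tables: F_f = IRF+SRF, F_RTC = RTC1+RTC2,
F_OCT = all four (3848 columns).

## Selection and classification protocol

Within each cross-validation fold, three rankers run on fold-train rows
only: Welch t-test and Wilcoxon rank-sum (exact p-values at total n ≤ 12,
tie-corrected normal approximation otherwise), each ordering features by
ascending p, and greedy mRmR in MID form (relevance minus mean
redundancy, mutual information in bits on tertile-discretized features).
Each emits a top-15 list; the two features with the lowest mean rank in
the three-way intersection are selected.  When the intersection has
fewer than two members — frequent when thousands of correlated features
compete, because mRmR deliberately avoids redundant near-duplicates of
the t-test/Wilcoxon leaders — the fallback is lowest mean rank over the
union of the top-15 lists, flagged in the audit.  All orderings break
ties lexicographically by name, making selection deterministic.

The evaluation protocol is a stratified 80:20 train/test split followed
by repeated (default 1000×) stratified 3-fold CV inside the training
portion.  Imputation and z-normalization are refit on fold-train only —
stricter than a cohort-wide normalization reading, chosen to exclude
leakage; run it cohort-wide by normalizing before `run_protocol` if
fidelity to that reading matters.  Four classifiers are fit on the two
selected features: LDA and QDA (QDA with reg_param 1e-4 for stability at
small folds), random forest (100 trees, seeded), and linear SVM whose
signed margin is logistic-squashed into [0, 1] (Platt scaling's internal
CV is unstable at fold sizes near 10).  AUC is the rank-based
(Mann–Whitney) statistic with ties at 1/2; accuracy, sensitivity and
specificity use score ≥ 0.5, rebounder positive.  Metrics are pooled as
mean ± sd over all iteration × fold evaluations; the best classifier is
flagged by CV mean AUC.  Held-out metrics on the 20% split are emitted
alongside, since published protocols of this shape are often ambiguous
about which of the two their tables report.

## Unsupervised assessment and decision gate

Feature tables are reduced to the leading principal-component scores
("top 10 features selected using PCA" is read as component scores, not
loading-ranked original columns; pass original columns to the clustering
functions directly for the other reading).  Component signs follow the
largest-loading-positive convention.  Hierarchical clustering uses
Ward/Euclidean linkage cut at two clusters, with clusters ordered by
rebounder share for stable reporting; K-means (10 restarts, seeded) runs
on the top two components with k chosen by the maximum discrete second
difference of the within-cluster sum of squares over k = 1..k_max,
flagged "weak elbow" when the best curvature does not double the
runner-up.  Composition is reported both as class percentages within
each cluster (rows sum to 100) and as the share of each class captured
per cluster.

The decision gate tabulates, per threshold t on the rebounder score
(score ≥ t → predicted rebounder), the percentage of each group
classified correctly; the rebounder percentage is non-increasing and the
non-rebounder percentage non-decreasing in t by construction.
`find_threshold` searches midpoints of sorted unique scores for the
operating point meeting a target percentage for one group while
maximizing the other group's percentage (for a non-rebounder target
that is the smallest qualifying threshold; for a rebounder target the
largest), and returns an explicit unreachable result otherwise.

## Synthetic cohort generator

No public cohort accompanies the problem, so the generator emulates the
study conditions: 11 rebounders and 17 non-rebounders by default, with
desk-scale 64 × 96 × 64 cubes (slices × depth × A-scans) standing in for
128-slice, 512-A-scan clinical scans (spacing defaults 94 × 20 × 94 µm).
Each eye gets:

* three smooth layer surfaces (unit-variance Gaussian-filtered noise,
  amplitude 3% of depth) with a central foveal ILM depression (8% of
  depth) and enforced ILM < EZ ≤ RPE ordering;
* 1–3 ellipsoidal IRF pockets clipped to the ILM–EZ band and 0–2
  lens-shaped SRF pockets (wide laterally, thin axially) clipped to the
  EZ–RPE band, centered in the middle 60% of the lateral extent —
  clipping guarantees a pocket never escapes its band, and an empty SRF
  compartment occurs naturally;
* multiplicative gamma speckle (shape 4, unit mean) over piecewise
  band reflectivities (vitreous 30, inner band 110, outer band 170,
  sub-RPE 60 on an 8-bit convention), fluid attenuated ×0.35;
* for rebounders only, zero-mean high-frequency noise (white noise
  minus its σ = 1 Gaussian local mean) added inside the IRF mask with
  amplitude `effect_size × 35` intensity units.

The effect noise comes from its own seed substream, so at
`effect_size = 0` the rendered volume is byte-identical whichever label
the eye carries: the null cohort is exchangeable by construction.  The
amplitude constant (35) is calibrated so that `effect_size = 2` is a
strong, reliably recoverable contrast: the rebounder median IRF Laws
E3S3S3 energy exceeds the non-rebounder value in ≈98% of paired draws,
and class contrast is monotone in `effect_size`.  Values near 1 are
borderline by design.

What the generator does *not* emulate: realistic layer-specific
reflectivity profiles, shadowing and vessel artifacts, scanner-specific
speckle correlation, segmentation error, or longitudinal change.
Passing recovery tests therefore show that the pipeline can detect and
localize a compartment-confined texture contrast of known size under
speckle — not that real rebounders carry such a contrast.

## Problem sizes in tests and acceptance runs

The recovery studies (label recovery, compartment-selection recovery)
run at 30 eyes per class, volume shape 12 × 48 × 32, and 100 CV
iterations — a scaled version of the default protocol chosen as the
smallest configuration at which the planted effect and the chance band
are cleanly separated.  At this size the full 962-descriptor extraction
takes well under a second per eye and a protocol run a few minutes on
one CPU.  Oracle-equivalence checks (per-voxel Haralick vs exhaustively
enumerated GLCMs, Laws vs dense 3D convolution, AUC vs concordant-pair
counting) run on ≤ 8³ volumes and score vectors of length ≤ 8, where
brute force is exact and fast.

## Known limitations

* The exact parameter grids behind the published 501 Laws and 383 Gabor
  counts are not recoverable; the manifest records one defensible
  enumeration and ships versioned, so results are reproducible even
  though the original grids are unknowable.
* Gabor filtering is 2D within B-scan planes (the anisotropic slice
  spacing makes 3D Gabor supports physically lopsided); the other three
  families are fully 3D.
* With 28 eyes, CV metric estimates carry large dataset-level variance;
  the chance band [0.35, 0.65] used for null checks reflects the
  30-per-class test size, not a universal bound.
* Per-voxel windowed GLCM is O(window³ × offsets) per voxel; at full
  clinical resolution (128 × 1024 × 512) a single eye is minutes of
  compute — batch runs should use the desk-scale default or a coarser
  window.
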