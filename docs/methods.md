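# Methods

## Problem and model

Hyperpolarized-gas (He-3 / Xe-129) ventilation MRI shows where inhaled
gas actually reaches the lung. In ex-smokers with and without COPD, the
*pattern* of ventilation — the patchiness of signal inside the thoracic
cavity and the number and size of unventilated "defect" clusters —
carries information about small-airway disease that spirometry does not.
The package implements an image-analysis and machine-learning pipeline
that turns a paired proton / gas acquisition into:

1. a thoracic cavity mask (seeded region growing on the proton image);
2. an intensity clustering of the gas image with the ventilation defect
   percent **VDP** (k-means, k = 5, defect = lowest-intensity cluster);
3. a greedy maximal-sphere decomposition of the unventilated region,
   yielding **VDCP** (defect-cluster volume as % of lung volume),
   **CDD1** (number of single-voxel defect spheres) and the **cluster
   slope** (log–log slope of cumulative sphere count against diameter);
4. a 496-entry radiomic feature vector (first-order, GLCM, GLRLM, GLSZM,
   GLDM, NGTDM, shape, four wavelet subbands, custom defect summaries);
5. Boruta all-relevant feature selection and a panel of classifiers
   (including RUSBoost) predicting *rapid decline*, defined as an
   annualized FEV1 loss ≥ 60 mL/year between two visits, each subject
   annualized over their own follow-up interval (boundary inclusive).

Because no clinical images ship with the package, a phantom generator
provides fully ground-truthed inputs; every algorithmic claim in the
test suite is made against planted truth or an independent brute-force
oracle.

## Sphere packing

The unventilated region `R` is tiled by discrete spheres. A sphere of
odd diameter `d` centred on voxel `c` contains every voxel `u` with
`||u − c||₂ ≤ (d − 1)/2` in voxel units, so `d = 1` is one voxel, `d = 3`
the 7-voxel face-neighbour ball, `d = 5` 33 voxels, `d = 7` 123 voxels.
The candidate diameter at a voxel is `d(v) = 2·⌈EDT(v)⌉ − 1`, where EDT
is the Euclidean distance to the nearest background voxel centre (grid
padded with background). The ceiling form is the correct discretization:
the inscribed radius `⌈EDT⌉ − 1` is strictly below the distance to
background, so containment is guaranteed, and an isolated planted ball
is recovered at exactly its planted diameter (the floor form would
recover a d = 7 ball as d = 5, since the EDT at its centre is √10).

Packing is greedy: all candidates at the current global maximum diameter
are accepted in lexicographic scan order (skipping any that would
overlap a sphere accepted in the same round), carved out, and the
process repeats until the maximum is 1; every remaining voxel becomes a
diameter-1 sphere. Consequences that hold *exactly* and are tested:
covered + residual = |R| (volume conservation); pairwise disjointness
(each voxel owned by at most one sphere); greedy is an approximation to
the minimum-cardinality cover, and no optimality is claimed.

Packing is performed in voxel space; the physical spacing (default 5 mm
isotropic) enters only through reported volumes. Strongly anisotropic
grids should be resampled before packing — the discrete-sphere
membership rule and the EDT would otherwise disagree about what a
"sphere" is.

The cluster slope is fit by least squares on
(log₁₀ d, log₁₀ #{spheres with diameter ≥ d}) over the diameters
present; with fewer than two distinct diameters it is undefined and
reported as NaN.

VDCP's denominator is the thoracic cavity volume (configurable); the
alternative (ventilated + defect volume) differs only through the
k-means partition.

## Segmentation choices

* Region growing accepts 6-connected neighbours whose intensity differs
  from the running region mean by at most `tolerance`, processing a FIFO
  frontier seeded from the sorted seed list — deterministic and
  seed-order invariant. A morphological closing (radius 1 by default)
  fills speckle holes.
* The ventilated ROI for texture extraction is the thoracic cavity
  thresholded at the Kapur maximum-entropy threshold of its 256-bin
  intensity histogram (the threshold maximizing the sum of below- and
  above-threshold Shannon entropies).
* k-means ventilation clustering is 1-D k-means++ with a fixed seed on
  the thoracic intensities; clusters are relabelled in ascending mean
  intensity and VDP is the fraction in cluster 1. Fewer distinct
  intensities than k reduce k with a warning; a constant image is all
  "defect" by the lowest-cluster convention.

## Texture engine

All matrix features are computed on an ROI discretized into 32
equal-width gray levels (fixed bin count; Idn and Idmn divide by the
gray-level count, so the bin count is part of the feature definition).
GLCM and GLRLM enumerate the 13 unique 3-D directions at distance 1,
compute per-direction features on the normalized matrix, and average;
GLSZM zones and GLDM dependences use 26-connectivity (GLDM threshold
α = 0). Undefined features on degenerate input (e.g. a single-voxel ROI
has no co-occurring pairs) are NaN sentinels with a warning, and the
pipeline imputes 0 before modeling.

The wavelet stage applies a single-level 2-D *stationary* (undecimated)
transform slice-by-slice along the third axis, keeping the four subbands
(LL/LH/HL/HH) aligned with the ROI; a 2-D slice transform is used
because exactly four subbands are wanted (a 3-D transform would give
eight). Default wavelet `coif1`; `haar` is used in hand-checked tests.
Odd slice extents are symmetric-padded to even and cropped back.

Shape features are voxel-based: volume from voxel counts, surface area
from exposed faces, axis lengths `4·√λ` from the population covariance
of voxel physical coordinates, and maximum diameters via convex-hull
point pairs. A single-voxel ROI has zero axis lengths, with
elongation/flatness 1 by convention.

The catalog is versioned ("1.0"): 94 features per image filter
(19 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM) on
the original image and the four subbands (94 + 376), 14 shape, and 12
custom defect summaries (VDP, VDCP, CDD1, cluster slope and
size-histogram statistics) = 496. The composition is fixed in the
manifest (`catalog_manifest()`); reported totals are properties of this
catalog, and the per-family split is this package's choice.

## Feature selection

PCA (eigen-decomposition of the covariance of standardized features,
population SD convention) is diagnostic only: it is reported, but the
modeled feature set comes from Boruta. How the two combine is a design
choice: all-relevant selection, not variance ranking, decides what the
classifiers see.

Boruta parameters: 200 trees, depth 10, at most 300 iterations, hit
threshold at the 95th percentile of shadow importances, α = 0.05, with
the two-step multiple-testing correction (step-up FDR plus a Bonferroni
bound) applied to two-sided Binomial(n, ½) tests on hit counts.
Tentative features at the cap are excluded downstream (conservative).
Three further choices matter for calibration:

* **Importance measure.** Feature importance is *holdout permutation
  importance*: each iteration the forest is fit on a random 70% of the
  rows and a feature's importance is the drop in mean correct-class
  probability on the held-out 30% when its column is permuted. Impurity
  (Gini) importance systematically rewards features whose association
  with the outcome is a fixed sampling accident of the dataset — such
  features beat freshly permuted shadows round after round and end up
  falsely confirmed. The holdout-permutation form measures
  out-of-sample contribution and keeps the false-confirmation rate at
  its nominal level in planted-recovery simulations.
* **Shadow-pool size.** Rejected features are dropped from the design
  matrix, but the shadow pool is padded (with additional independent
  permutations of the surviving features) back to the original feature
  count. If the pool were allowed to shrink, the 95th-percentile
  threshold would collapse toward the maximum of a handful of noise
  draws late in the run, and surviving noise features would start
  hitting at well over the null rate.
* **Forest backend.** The forest is LightGBM in random-forest mode
  (bagging fraction 0.632 per tree, per-tree feature subsampling at the
  √p rate, minimum leaf size 5), honouring the tree count and depth
  above. The importance measure is model-agnostic, so the backend
  choice affects runtime, not the selection semantics.

Decisions are invariant to the column order of the input table: features
are processed in sorted-name order and every permutation stream is keyed
by feature name.

## Classifiers and evaluation

Ten families are registered: logistic regression, Gaussian naive Bayes,
RBF SVM with the "medium" kernel scale √p (γ = 1/p on standardized
inputs), decision tree, cosine-metric KNN, bagged trees, AdaBoost-ed
trees, random-subspace LDA and KNN ensembles (30 learners on random
feature halves), and RUSBoost. RUSBoost is implemented directly: each
boosting round draws all minority rows plus a weighted random
undersample of the majority class down to the minority count, fits a
depth-limited tree, computes its weighted error on the full training
set, and applies the standard AdaBoost multiplicative weight update;
scores are weighted vote margins mapped to [0, 1]. Rounds with weighted
error ≥ ½ are skipped.

Training uses a label-stratified 80/20 split and stratified 5-fold
cross-validation, with a small documented hyperparameter grid per family
searched by mean CV AUC (in place of an interactive optimizer). Test-set
metrics come from the confusion matrix at threshold 0.5 on calibrated
scores plus the midrank (Mann–Whitney) AUC. Correlated AUCs of two
models scored on the same test subjects are compared with the DeLong
test (structural-components variance estimator, midranks for ties,
two-sided p); identical score vectors return p = 1 with a warning.
Group comparisons gate on Shapiro–Wilk normality at α = 0.05 per
variable (Welch t when normal, rank-sum otherwise) with
Benjamini–Hochberg adjustment across the variable set;
Holm–Bonferroni is available for the selected-feature comparisons.

## The phantom generator

The generator emulates the study conditions, not anatomy:

* **Geometry.** A torso ellipsoid (bright on the proton image, signal
  200) containing two lung ellipsoids (signal 60, eroded to keep a ≥ 2
  voxel bright shell), on a 64×64×14 grid at 5 mm isotropic spacing.
* **Ventilated texture.** A Gaussian random field smoothed at a
  configurable correlation length, normalized to unit variance and
  applied multiplicatively: `signal = 100·(1 + a·G)`, clipped positive.
  The amplitude `a` and correlation length control gray-level
  heterogeneity, hence the GLCM/GLDM feature values.
* **Defects.** Unions of planted discrete balls (odd diameters, placed
  with ≥ 1 voxel of background between balls so each is exactly
  recoverable by the packing algorithm) plus scattered single voxels.
  The truth inventory records every planted sphere, making
  packing-recovery tests exact.
* **Noise.** Rician (magnitude-MRI) noise at SNR 15.
* **Cohort.** 57 "stable" and 31 "rapid" subjects by default. Covariates
  are drawn from group-specific normals matching the published
  demographics of such cohorts (e.g. FEV1 2.2 ± 0.8 L stable vs
  2.5 ± 0.8 L rapid; FVC 3.4 ± 0.9 vs 3.9 ± 0.8 L). Two-visit FEV1
  pairs are built from a truncated-normal annualized decline —
  stable: 15 ± 25 mL/yr truncated to (−80, 55); rapid: 120 ± 45 mL/yr
  truncated to (65, 300) — over a 31 ± 7 month interval, so the
  ≥ 60 mL/yr labeling rule reproduces the group assignment exactly.
* **Group effects.** Rapid decliners carry a larger defect burden
  (18 ± 5% of lung voxels vs 10 ± 4%), more and larger planted balls,
  a shorter texture correlation length (2 vs 3 voxels) and a higher
  heterogeneity amplitude (0.40 vs 0.20). These directions reproduce
  the clinical pattern: higher low-gray-level emphasis features
  (LGLZE/SRLGLE/SDLGLE), higher CDD1 and VDP, lower local homogeneity
  (Idn/Idmn) in the rapid group. The published study does not report
  per-group defect-size distributions, so the magnitudes are this
  package's calibration — chosen so that the planted signal is clearly
  detectable at n = 88 — and are configuration, not a claim about any
  cohort. A `null` configuration with identical group distributions
  exists for type-I-error checks.

**What passing tests show and do not show.** The phantoms have clean
ellipsoidal geometry, stationary Gaussian texture and exactly planted
defects; real ventilation MRI has anatomy, coil shading, motion and
acquisition artifacts. Green tests therefore demonstrate that the
algorithms are implemented correctly and recover planted effects of
realistic direction and size — not that the classifiers would reach any
particular accuracy on clinical data.

## Problem sizes and determinism

The demo cohort (88 phantoms on 64×64×14 grids) runs end-to-end in a
few minutes on one CPU; oracle comparisons use 6×6×3 grids where brute
force is exact and fast; packing stress tests use ~100 random masks of
18×18×14. All stages are seeded — phantoms, k-means, splits, Boruta,
every classifier — and a rerun of the same configuration reproduces the
report byte for byte (the report carries the seed, a config hash and
the catalog version; no timestamps).

## Known limitations

* Packing assumes isotropic voxels (see above).
* The 496-feature catalog reproduces published *totals*; the exact
  per-family composition of the original feature set is not public, so
  feature-by-feature numeric comparability is not claimed.
* The greedy sphere cover is not minimal-cardinality.
* Boruta on very small training sets (< 20 rows) is refused rather than
  attempted.
* DeLong's normal approximation is used as-is; at very small n its p
  is approximate (checked against a paired bootstrap at n = 12).
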