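# Methods

## Overview

`glandring` quantifies the tissue architecture around glandular lumina in
soft-classified histology images. The input is not an RGB image but a stack
of K per-pixel class posterior maps (for breast/prostate tissue typically
lumen, epithelium, nuclei and stroma), produced upstream by any stain
decomposition or pixel classifier. The package's core feature — ring-based
statistical proximity sampling — describes *what surrounds each lumen and in
what order*, which is the information a pathologist uses when judging
tubule formation (the tubularity component of Elston and Gleason grading).

## Proximity sampling

Lumen regions are obtained by binarizing the lumen posterior channel
(default: a pixel is lumen iff the lumen posterior is the per-pixel
maximum, ties resolved toward lumen) and labeling 4-connected components —
diagonally touching pixels are *not* merged, so adjacent but distinct
luminal spaces stay separate instances.

Each region is dilated by a 3×3 square structuring element in sequential
unit steps. The set difference of successive dilations yields concentric
annuli that preserve the lumen's shape while marching outward (optionally
inward, by erosion shells, or both). For ring r the fraction of class k is

    f_{r,k} = (Σ_{p ∈ ring r} P_k(p)) / |ring r|,

the posterior mass of class k divided by the ring area. Ring areas are the
*in-image* pixel counts, so border-clipped rings still yield proper
distributions; a fully clipped (empty) ring contributes an all-zero row and
is flagged in the feature's metadata, keeping dimensionality fixed. The
originating region is excluded from its own rings, but *other* lumen
regions are sampled like any tissue class — a nearby gland shows up as
lumen signal at the ring index corresponding to its distance, which is
informative (cribriform growth, crowded glands).

The per-ring K-vectors are stacked class-major into a single R×K feature:
entries 1..R are the lumen fractions of rings 1..R, then epithelium, and so
on. Defaults are R = 10 rings and the 3×3 unit step; coarser steps are
equivalent to area-weighted pooling of adjacent unit rings (verified as an
invariant in the tests), trading spatial resolution for noise reduction.

## Scalar shape baseline

Four classical descriptors are computed per lumen region for comparison:

* **size** — pixel count;
* **bending energy** E_b = Σ κ²(p) ds over the closed boundary, where κ is
  the Gaussian-smoothed turning-angle signal of the 8-directional Freeman
  chain code per unit arc length (diagonal steps weigh √2). A circle of
  radius R attains the minimum 2π/R; spiky or irregular outlines score
  higher.
* **area-to-perimeter ratio** 4πA/P², ≈1 for circles, π/4 for squares,
  small for elongated regions;
* **convexity (solidity)** A_region / A_convex-hull, computed on the
  pixel-corner polygon so filled rectangles score exactly 1.

Numerical choices: the boundary is traced by Moore neighbor tracing with a
first-edge-repetition stopping rule (robust on one-pixel-wide spurs);
turning angles are wrapped to (−π, π] before smoothing; the smoothing width
defaults to σ = 4 boundary samples. σ was chosen against the circle closed
form: the chain code of a digital circle is a staircase whose unsmoothed
turning signal grossly overestimates curvature energy, and σ = 4 keeps the
discrete E_b within ~4% of 2π/R for radii 20–80 while leaving shape-scale
concavities intact; smaller widths (σ ≤ 2) leave up to ~50% staircase
bias at radius 50. One-pixel regions define E_b = 0 and 4πA/P² = 1. Small
regions can exceed 1 in 4πA/P² — a discretization artifact of chain-code
perimeters, not clamped.

## Bags and dissimilarity space

An image is a bag of per-lumen proximity features; only the bag carries a
grade (C0 = tubule-absent, C1 = tubule-present). The distance between bags
is the linear assignment distance: instances of the smaller bag are
matched one-to-one onto distinct instances of the larger bag minimizing
total instance distance (Euclidean by default; cityblock available), and
the *mean* matched distance is reported. The mean (rather than the sum)
avoids penalizing instance-rich images purely for size; surplus instances
of the larger bag are ignored. The N×N bag dissimilarity matrix is then an
ordinary feature matrix — row i represents bag i by its distances to the
other bags — so any vector-space classifier applies unchanged.

The scalar shape baseline travels through the same machinery, with one
extra step: its four features mix scales (a pixel count next to three O(1)
ratios), so instances are z-scored over the dataset's pooled instances
before distances are computed. This global scaling slightly favors the
baseline (it sees pooled statistics), which is acceptable for a
comparison it still loses.

## Evaluation protocol

A stratified random 25% of the bags is set aside for hyperparameter
tuning; SVC (linear kernel, C over 10⁻²..10²) and k-NN (k ∈ {1,3,5,7}) are
tuned there by leave-one-out, ties resolved toward the less complex
setting (smaller C, larger k). The remaining bags are scored by stratified
10-fold cross-validation repeated 5 times; accuracies are reported as
mean ± std over repeats, in percent. Four classifier families are run on
the identical dissimilarity matrix: linear SVC, k-NN, logistic regression
and a normal-based linear discriminant (shrinkage LDA), all delegated to
scikit-learn behind a thin adapter.

In every fold, a bag's features are its distances to that fold's
*training* bags only; test-to-test distances are never used (verified by a
poisoning test), so the representation leaks no test information.
Stratification keeps both classes in every training fold.

## Unsupervised model-order selection

Pooled instances are clustered by full-covariance Gaussian mixtures
(reg_covar = 10⁻⁶) for k = 1..10. Each k is fit from 10 random restarts
(initial means drawn from the data; purely random responsibilities make EM
collapse onto merged components and were rejected), every restart scored
separately so the criterion curves carry error bars:

    BIC = −2 ln L + k ln n        AIC = −2 ln L + 2k

with n the number of instances and k the number of *clusters*. Counting
clusters rather than free parameters is a deliberate, light penalty; the
textbook parameter-count penalty is available via `penalty="parameters"`.
The best k minimizes the mean criterion (ties to the smallest k). Because
the two criteria share the same likelihood curve and AIC's penalty is
lighter for n > e², AIC's minimizer is never below BIC's.

A known limitation of the cluster-count penalty: it does not grow with the
data dimension, while the overfitting gain of an extra full-covariance
component does (≈ d(d+3)/4 nats). Recovery of a true k therefore degrades
as d grows — at d = 2 and n = 500 the criterion already over-selects in
most replicates. The model-order recovery study in the acceptance suite
uses univariate two-component mixtures (separation 6σ, n = 500), where
recovery is reliable; with the parameter-count penalty it is reliable in
any dimension. Bag labels in the unsupervised route are the majority
cluster over a bag's instances, ties to the lowest cluster index.

## Synthetic tissue generator

The generator produces the study conditions for every desk-scale
experiment. A C1 image contains 1–37 (default draw 2–8) star-convex lumen
polygons (12 vertices, radius 5–9 px, ±30% radial jitter) wrapped in a
4 px epithelium shell then a 3 px nuclei shell, embedded in stroma; shells
follow the lumen's shape via the Euclidean distance transform, with
overlapping neighborhoods resolved by nearest lumen. A C0 image has the
same lumen geometry but each gland's two shell classes are scrambled (a
random draw of two distinct classes from {epithelium, nuclei, stroma}),
and the displaced class material is re-deposited as irregular background
blobs so the *marginal* class proportions match C1 closely (verified to
within 3 percentage points). The classes therefore differ only in spatial
organization — exactly the signal proximity sampling encodes and
per-pixel composition histograms cannot see.

Posteriors are Dirichlet-noised indicators: the true class's concentration
parameter is 1 + c (default c = 30, giving ≈0.91 mean posterior on the
true class), the others 1; `c = None` yields crisp one-hot maps. Channel
order is fixed (lumen first), so the extraction pipeline for synthetic
data disables mean-intensity channel reordering — that heuristic assumes
lumen-dominant staining, which small crisp glands on a stroma background
do not satisfy.

What the generator does **not** emulate: real stain spectra and
decomposition noise, touching/merging glands, tissue folds and artifacts,
within-class texture, and annotator label noise. Passing the end-to-end
tests shows the pipeline recovers *spatial-organization* differences under
soft posteriors; it does not certify accuracy on real stained tissue.

## Problem sizes

Desk-scale defaults keep every experiment on one CPU in seconds to a few
minutes: 128×128 px images, 25 images per class (50 bags), 10 rings,
5×10-fold evaluation; model-order scans use n = 500 instances, k ≤ 10,
10 restarts, 20 replicates. All stochastic steps are seeded and every
report records its seeds.
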