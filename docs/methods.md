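# Methods

This note documents the models, defaults and design choices behind embow,
and what the synthetic experiments do and do not demonstrate.

## Image model and synthetic generator

The pipeline assumes standardized input: grayscale images on a common
canvas, with the specimen aligned so that a fixed location on the canvas has
a fixed anatomical meaning. The synthetic generator emulates exactly this
regime: a 192×96 8-bit canvas (2:1, embryo-like), an elliptical specimen
mask with semi-axes (88, 40) pixels centred on the canvas, base intensity 40
inside the mask and exactly 0 outside, and hard-edged expression patterns
drawn at intensity 150 above base. Patterns are parameterized in
embryo-normalized coordinates over the ellipse's bounding box, so a pattern
keeps its position relative to the pooling grid in every image. Four default
terms map one-to-one to patterns occupying distinct regions (three vertical
stripes; an anterior spot; a posterior band; a dorsal band); a fifth
(ventral band) is added for retrieval experiments. Per-image variability is
additive Gaussian noise inside the mask (default SD 20 of 255, clipped) and,
optionally, a Gaussian positional jitter of the pattern location (SD 0.02
normalized units for annotation, 0.03 for retrieval). Jitter stands in for
the residual biological/alignment variability of real collections; without
it, images of a class are identical up to noise and retrieval is trivially
perfect in every mode.

What the generator does **not** emulate: staining artifacts, rotation/scale
misalignment, multiple views, intensity gradients across specimens, or
correlated term co-occurrence (terms are drawn independently per group).
Passing tests therefore show that the implementation recovers spatially
localized, independently occurring patterns under additive noise and small
positional jitter — not that it reaches any particular performance level on
real curated image collections.

## Patches and descriptors

Patches are circles of radius 16 px on a regular grid with stride 16
(= radius, 50% linear overlap), starting at (radius, radius) and keeping
centres with x ≤ W−r, y ≤ H−r. A centre on that upper boundary overhangs
the discrete pixel grid by one row/column, which is treated as zero
background. Pixels outside each circle are zeroed before description:
the support really is the disk, not its bounding square.

The descriptor is an upright SIFT: 4×4 spatial bins × 8 orientation bins
over the 33×33 patch, Gaussian-weighted with σ = radius/2, trilinear
interpolation in space and orientation, L2 normalization, clipping at 0.2,
renormalization; d = 128. Orientation is deliberately *not* normalized to a
dominant direction — the images are pre-aligned and rotation invariance
would discard exactly the information the spatial pooling uses. Gradient
magnitudes are restricted to the disk interior (distance ≤ r−1), so the
circular mask edge contributes nothing and a flat patch yields the zero
vector, which is flagged and excluded from codebook training and encoded as
a zero row. This interior restriction also makes per-image gradient slicing
bit-identical to per-patch computation (tested), which is the fast path.

## Codebook

k-means over descriptors pooled from a seeded random subset of images
(default fraction 0.15 in the experiments). Initialization is k-means++
(scikit-learn's `kmeans_plusplus`); the Lloyd iterations run in-package so
the objective trace is recorded and checked to be non-increasing, with
empty clusters reseeded deterministically to the farthest point. Ten seeded
restarts, best objective kept. Centroids are stored un-normalized so sparse
reconstruction errors stay in descriptor units. The nominal codebook size is
2000; all experiments here use c = 50 (and unit tests less), which is ample
for the synthetic patterns and keeps the whole suite fast on one CPU.

## Sparse coding

The visual-sentence code solves min_x ½‖Dx − y‖₂² + λ‖x‖₁, x ≥ 0, λ = 0.01.
The squared residual form is used; with the one-sided soft-threshold
coordinate update this is the standard non-negative lasso. The solver is
cyclic coordinate descent on the Gram formulation, initialized at x = 0,
stopping when the relative objective decrease falls below 1e-10 on every
problem or after 10 000 sweeps; zero-norm dictionary columns are excluded.
Whole image sets are encoded as one batched solve (the coordinate update
vectorizes across problems sharing D). Correctness is established against a
support-enumeration oracle (exact global minimum for small c) to 1e-6 in
objective, plus KKT limit cases (x = 0 for λ ≥ max_j D_jᵀy; x = y for an
identity dictionary at λ = 0) and the monotone regularization path. The
batched and one-at-a-time solves agree to the stopping tolerance, i.e. to
about 1e-5 in x, not bit-for-bit — tests compare accordingly.

Hard assignment breaks distance ties toward the lower word index. Flat
(zero) descriptors encode to the zero vector in both modes rather than to
an arbitrary word; the hard global bag therefore sums to the count of
non-flat patches.

## Pooling

Spatial cells are half-open rectangles of size ⌊W/cols⌋×⌊H/rows⌋ with the
last row/column absorbing remainder pixels; a centre exactly on an interior
boundary belongs to the higher-index cell. Per-cell column sums of the code
matrix are concatenated row-major; the 3×6 grid (the default) multiplies
the representation length by 18. Block-sums reproduce the global bag
exactly for hard counts and to 1e-9 for sparse codes (tested per image).
Group vectors are element-wise sums over the group's images, L1-normalized
by default so group size does not scale the features. Only the single 3×6
level is used — no multi-level pyramid weighting.

## Annotation protocol

Terms are ranked by frequency (ties alphabetical); the top-n are retained
and groups carrying none of them are dropped. Partitions split groups ~1:1
with per-term stratification: terms processed in frequency order, each
unplaced positive going to the side with fewer of that term's positives,
followed by a size-rebalancing pass and a bounded swap-repair pass run on
the labels and their complements, so both classes of every term stay
balanced (within ±1 on randomized checks) without disturbing the 1:1 size
split. Exact simultaneous stratification of overlapping labels is
infeasible in general; this greedy-plus-repair scheme is the package's
choice.

Classifiers are linear: SVM (squared hinge, primal, C = 1 default),
logistic regression, or ridge; one binary model per term. For the
classifier-comparison mode, regularization is selected per term by 4-fold
cross-validation over {0.01, 0.1, 1, 10, 100}, scored by validation F1.
Over-sampling draws positives with replacement until they match the
negative count, leaving negatives untouched. AUC is computed from decision
scores (rank form with tie averaging); F1, sensitivity and specificity use
the sign of the decision function (threshold 0). Macro averages are
unweighted over terms; tables report mean ± SD of the macro values across
partitions.

Known limitation: with L1-normalized features the entries scale as 1/length,
so spatial (18×J-dimensional) features are small in magnitude and a C = 1
linear SVM produces under-confident scores; at threshold 0 this depresses
F1/sensitivity even when AUC is near 1. The threshold is kept at 0 (no
calibration) because the protocol specifies none; AUC is the
threshold-independent headline metric.

## Retrieval

Per-image (not per-group) vectors, L1-normalized, compared by cosine
similarity — the standard bag-of-words choice, which makes self-similarity
exactly 1 and is the stated reason queries are removed from their own
result lists. Top-k with k = 8, ties broken by image id. Precision@8 over
labelled pattern clusters is the evaluation statistic.

## Problem sizes in the shipped experiments

Annotation study: 200 groups × 2 images, 4 terms at prevalences
0.5/0.45/0.4/0.3, noise SD 20, jitter 0.02, codebook c = 50 from a 0.15
image sample, 10 partitions. Retrieval study: 5 single-pattern clusters ×
20 images, noise SD 20, jitter 0.03, same codebook size. These sizes were
chosen as the smallest at which the per-term positive counts and cluster
structure are comfortably estimated; both studies together run in about two
minutes on one CPU. The tests and `scripts/acceptance.py` recompute every
reported number at run time.
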