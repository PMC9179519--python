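# Methods

`dualrad` implements a dual-purpose computer-aided-diagnosis chain for
breast-ultrasound images: one convolutional autoencoder that both segments
the lesion and emits a compact "deep radiomic" descriptor, a conventional
radiomics extractor, a spectral dimensionality-reduction step, and a
random-forest diagnosis harness evaluated by leave-one-out
cross-validation (LOOCV).  This note records the model, the defaults, the
numerical choices, and what the synthetic phantoms do and do not establish.

## The dual autoencoder

The network maps a grayscale image x (512×512 at full scale) through a
contracting path of convolutional blocks (3×3 kernels, batch
normalization, ReLU, 2×2 max-pooling) to a bottleneck, then mirrors back
through an expanding path (nearest-neighbor upsampling + convolution) to a
sigmoid probability map y the size of the input.  There are no skip
connections, so everything the decoder produces is a function of the
bottleneck alone.  The bottleneck flattens the final feature volume and
passes it through a dense hierarchy down to a 16-unit linear latent vector
η = F_e(x); the decoder reconstructs from η via the mirrored dense
hierarchy, y = G_d(η).  One forward pass therefore yields both the
segmentation and the latent descriptor, and `predict` returns exactly the
activations the encoder alone would produce (asserted as an invariant).

**Geometry.** Channel widths double per block from `base_filters`, capped
at `max_channels`; only the blocks after the stem pool, so five
convolutional blocks perform four halvings.  Under the full-scale (`paper`)
preset — 512×512 input, 32 base filters, cap 256 — the encoder ends at
32×32×256, a flattened width of 262,144, compressed by the dense hierarchy
262,144 → 256 → 16.  The parameter count (~1.4×10⁸) is reported by
`model_summary` without allocating the network.  The `desk` preset
(64×64 input, 8 base filters, dense hidden 64, ~4.6×10⁵ parameters) is the
configuration every test and benchmark trains; it keeps a full training run
in the tens of seconds on one CPU core.

**Objective.** Training minimizes the soft Dice loss with squared
denominator terms,

    DSC(p, g) = 2·Σ pᵢgᵢ / (Σ pᵢ² + Σ gᵢ²),    loss = 1 − DSC,

computed per sample and averaged over the batch.  A smoothing constant
ε = 1 is added to numerator and denominator during training so the
empty/empty case is well defined and gradients stay bounded; the *metric*
`dice_coefficient` uses no smoothing (the empty-vs-empty case is defined
as 1.0 directly).  Optimization is Adam with a cosine learning-rate decay
from `lr_start` to `lr_end`.  The full-scale defaults are 150 epochs, batch
8, 2×10⁻⁴ → 10⁻⁶; the desk benchmark uses 30 epochs at 3×10⁻³ → 10⁻⁴,
scaled to its ~2000× smaller model.  Normal (lesion-free) images are
excluded from segmentation training by default because an all-zero ground
truth makes the Dice target degenerate; a flag re-admits them.

The implementation is a compact pure-NumPy layer stack (im2col
convolutions, manual backpropagation) in `dualrad._nn`; it is deliberately
sized for CPU training and is checked against finite-difference gradients
layer by layer.

**Latent filtering.** After training, most latent units are dead (exactly
zero) or nearly constant.  `filter_latent` drops exactly-zero columns and
keeps the k = 4 highest-variance remaining columns (ties toward the lower
index), yielding the "deep radiomics" fed to the classifier.

## Conventional radiomics (354 features)

Computed strictly inside the lesion mask: on the original image,
first-order statistics (18), 2-D shape (9), GLCM (24), GLDM (14),
GLRLM (16), GLSZM (16) and NGTDM (5) — 102 features; plus first-order
statistics on 14 derived images (Laplacian-of-Gaussian at σ ∈ {1, 3} and
the 12 sub-bands of a 3-level stationary `db2` wavelet transform) — 252
features; 354 in total.  This is the unique clean decomposition reaching
354 with a three-level wavelet when derived images contribute first-order
statistics only; the manifest (`feature_names`) is frozen and ordered.

Numerical conventions:

* gray levels: fixed bin count (32) over the ROI intensity range, which
  makes all matrix-based features invariant to affine intensity rescaling
  (asserted in tests);
* matrix definitions follow the common IBSI-style formulations; GLCM pools
  each offset with its negation (symmetric) and averages scalars over the
  four distance-1 directions; GLDM uses dependence threshold α = 0; zones
  and dependencies use 8-connectivity;
* degenerate ROIs: entropy-type features → 0, ratio-type features → their
  limiting value (e.g. GLCM correlation → 1 for a constant ROI), never NaN;
* the LoG kernel is the analytic formula sampled to radius 5σ with its
  mean subtracted, so constant images map to an exactly zero response while
  an impulse reproduces the closed-form kernel to ~10⁻⁸;
* the shape perimeter uses the 4-direction Crofton estimator (staircase
  bias ≈ 2–3% on a disk instead of ~15% for the marching-squares polygon
  length); mesh surface is the shoelace area of the marching-squares
  boundary.

## Spectral reduction

Features are z-scored per column, a k-nearest-neighbor graph (k = 10,
union-symmetrized) is built with Gaussian weights
exp(−d²/width²) — width defaults to the median retained-edge distance, a
scale-free choice — and the generalized eigenproblem L v = λ D v of the
graph Laplacian is solved (sparse shift-invert; a dense solver serves as
the test oracle).  The eigenvectors of the 12 smallest nontrivial
eigenvalues form the embedding (trivial constant vector dropped; each
eigenvector's largest-magnitude entry is made positive).  Disconnected
graphs — possible under LOOCV subsampling — are regularized by adding a
uniform 10⁻⁸ affinity, with a warning.  `elbow_select` suggests a
component count by the maximum perpendicular distance from the eigenvalue
curve to its end-to-end chord (ties toward the smaller count).

**Out-of-sample cases.** Laplacian eigenmaps has no native extension to
unseen points.  The left-out case of a LOOCV fold is placed by a
Nyström-style rule: the affinity-weighted average of its k nearest training
embeddings.  This is a pragmatic remedy, stated loudly: embedding train and
test jointly (transductive mode) is implemented but is *not* the default,
because it leaks test information into the fitted stage.

## Classification and evaluation

A random forest classifies benign (0) vs malignant (1) from the 12
embedded conventional features, the 4 deep features, or their 16-wide
concatenation, under LOOCV: each case predicted by a forest fit on all
others, with the per-fold spectral reduction refit on the training rows
only.  The default hyperparameter grid has six settings of
(trees, depth, random state): (10, 2, 10), (25, 3, 30), (15, 4, 65),
(22, 5, 80), (22, 6, 80), (22, 6, 90); evaluating all of them on all three
feature sets gives the 18-row results table.  The random state is both a
grid dimension and the forest's RNG seed — statistically unusual, but kept
intentionally as part of the grid's definition.  A stratified 5-fold grid
search (`kfold_grid_search`) is available to confirm a setting (ties
prefer fewer trees, then shallower depth).

A single LOOCV pass yields one accuracy number, so "median (IQR)" is
defined here over 1000 case-level bootstrap resamples of the
(prediction, label) pairs — the only reading that produces a distribution
without re-running training.  Cohen's κ is summarized as mean ± sd over
the same resamples (κ := 0 with a warning when the marginals are
degenerate).  Between-setting contrasts use a two-sample two-tailed t-test
on the bootstrap accuracy samples.  Ranking quality is the step-wise
average precision of the forest vote fraction.  Per-feature group
differences use the two-sided rank-sum test (exact null for groups ≤ 10
without ties, tie-corrected normal approximation otherwise; raw p-values
by default with an optional Benjamini–Hochberg flag).  Normal cases take
part only in segmentation data, never in classification.

## The phantom generator

The synthetic cohort emulates the *structure* of a clinical
breast-ultrasound dataset: per-class folders of grayscale PNGs with binary
lesion masks, default class counts 437 benign / 210 malignant / 133
normal (780 images).  Each image is a smooth tissue base (slight depth
gradient plus a large-scale random field) modulated by spatially smoothed
multiplicative Rayleigh speckle.  Lesions are hypoechoic (interior
intensity ×0.5 by default), star-convex and single-component: benign
lesions are smooth ellipses; malignant lesions add a radial sinusoidal
boundary perturbation (spiculation, amplitude 0.25 by default, area-
renormalized) and posterior acoustic shadowing in half the cases.  Every
sample is a pure function of (seed, case index, label), so cohorts are
bit-reproducible.  An `easy_segmentation` configuration (64×64, large
central high-contrast lesions, mild speckle) defines the desk-scale
segmentation benchmark.

What the phantoms do **not** model: attenuation and beam physics, acoustic
artifacts other than a schematic shadow, operator variability, multiple or
non-star-convex lesions, and the intra-class heterogeneity of real tumors.
Passing tests on phantoms therefore demonstrates that the machinery is
correct and that the chain recovers a planted class signal — not that the
reported accuracies transfer to clinical data.

## Problem sizes used in tests and the acceptance script

All benchmarks run the desk preset: the segmentation benchmark trains on
60 easy phantoms for 30 epochs and evaluates 30 held-out phantoms (three
seeds, majority); the end-to-end run pushes 200 phantoms (100 benign /
100 malignant, 64×64, default morphology) through the full chain with 20
training epochs and a 500-replicate bootstrap.  These sizes keep a full
suite run in minutes on a single CPU core while leaving every stage
nondegenerate.

## Known limitations

* The full-scale (512×512) preset is provided and geometry-checked, but
  training it is outside what the NumPy backend is meant for.
* The Nyström extension is an approximation; cases far from the training
  manifold are pulled toward the mean of their nearest neighbors.
* LOOCV accuracy on permuted labels is slightly pessimistic (the left-out
  case's class is under-represented in training), which the null-band
  checks absorb.
* GLCM `Idmn`/`Idn` normalize by the number of observed gray levels, so
  they are not comparable across ROIs quantized to different effective
  level counts.
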