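# Methods

## Problem setting

The package targets classification problems where each sample is described
by two real-valued feature views — the motivating case is dementia staging
from brain MRIs, where two convolutional networks each emit a ~1280-dim
feature vector per image and the four classes are non-, very mild, mild,
and moderate demented.  The pipeline (a) fuses the views with canonical
correlation analysis (CCA), (b) selects a compact feature subset with a
binary-enhanced whale optimization algorithm (bE-WOA) driven by a
k-nearest-neighbor (kNN) wrapper fitness, and (c) evaluates with
confusion-matrix rates over repeated train/test splits.

The package does not extract deep features; it ingests feature tables
(CSV with a `label` column) and ships a synthetic generator so the whole
pipeline is testable without external data.

## CCA fusion

Given centered views `X (n x p1)` and `Y (n x p2)`, CCA maximizes
`corr(X a, Y b)` over weight pairs, classically via the generalized
eigenproblem on `Cxx^{-1} Cxy Cyy^{-1} Cyx`.  We solve the equivalent
symmetric form: Cholesky-whiten each regularized within-view covariance,
`K = Lx^{-1} Cxy Ly^{-T}`, and take the SVD of `K`; singular values are
the canonical correlations (non-increasing, in [0, 1]), and the
back-transformed singular vectors are the projections.  Tests assert
equivalence with a direct eigensolve and with a derivative-free numeric
maximization of the correlation objective (1e-4 agreement).

Numerical choices:

* **Ridge.**  Deep-feature covariances (p ≈ 1280, n a few thousand) are
  singular, so each covariance gets `ridge = 1e-6 * trace(C)/p` added to
  its diagonal by default (overridable, including 0, which raises a
  rank error on singular input).  Training components have unit variance
  under the regularized covariance.
* **Components.**  `fit_cca` defaults to `d = min(p1, p2, n-1)` truncated
  to the numerical rank (singular values above `1e-10` of the largest);
  `max_components` caps it.  The *pipeline* additionally truncates to the
  number of statistically significant canonical pairs by Bartlett's
  sequential chi-square test on Wilks' lambda
  (`component_rule="bartlett"`, the default; `"rank"` keeps everything).
  Rationale: with views of moderate dimension, most canonical pairs are
  chance-level, and whitening gives them the same unit variance as the
  signal pairs — retaining them drowns the kNN distance structure and can
  make the fused representation worse than a single raw view.  A fused
  width slightly below `2*min(p1,p2)`, as observed with deep features in
  practice, is itself evidence of such truncation.
* **Fusion mode.**  `concat` (width `2d`) is the default because it
  preserves view-specific components; the summed form `Wx'x + Wy'y`
  (width `d`) is provided as `sum`.
* **Scaling.**  Mean-centering only by default; optional z-scoring
  (`scale=True`).  Canonical correlations are invariant to invertible
  affine column re-scaling when `ridge = 0`, which is property-tested.

## Whale optimization

The conventional WOA (continuous, box-bounded minimization) updates each
whale per iteration by one of three moves selected by a switch draw
`sigma ~ U(0,1)` and coefficient `W = 2 w rand - w` with
`w = 2 - 2k/MaxIt`:

* encircling prey (`sigma < 0.5`, `|W| < 1`): `Ybest - W |C Ybest - Y|`;
* search for prey (`sigma < 0.5`, `|W| >= 1`): same form against a random
  population member;
* spiral attack (`sigma >= 0.5`): `|Ybest - Y| e^{cl} cos(2 pi l) + Ybest`
  with `l ~ U(-1,1)` and spiral shape `c = 1` by default.

`C = 2 rand` per whale per iteration; positions are clipped to bounds;
the switch uses `|W|` since `W` is symmetric about 0 by construction.
Best-so-far fitness is recorded per iteration and is non-increasing by
construction.

### Binary-enhanced WOA

For feature selection the enhanced variant adds:

* **Pool** (capacity = population size by default): once per iteration a
  crossover candidate `B ∘ Ybrnd + B̄ ∘ Yworst` is archived, where `B` is
  a random binary vector and `Ybrnd` a Gaussian perturbation of the best
  position with scale `0.1 (upper - lower)`; a full pool replaces a
  uniformly chosen member.
* **Migrating search**: each iteration a random `ceil(0.1 N)` whales are
  re-seeded as `Yrnd - Ybrnd`, uniform draws from the global box and from
  a `±0.1`-width neighborhood of the best position.
* **Preferential selection** (`sigma < 0.5`, `|W| >= 0.5`):
  `Y + W U (P1 - P2)` with distinct pool members `P1, P2` and `U = 2 rand`.
* **Enriched encircling** (`sigma < 0.5`, `|W| < 0.5`):
  `Ybest - W |C Ybest - P3|` with a random pool member `P3`.

The binary dispatch threshold on `|W|` is 0.5 (the enhanced variant's
convention) versus 1 in the conventional WOA.  Continuous positions in
`[-4, 4]` are the dynamical state; each evaluation maps the position
through a transfer function — S-shaped `sigmoid(y)` by default, V-shaped
`|tanh(y)|` selectable — and samples bits `b_i = 1 iff U(y_i) >= rand`.
A per-whale greedy rule keeps whichever of the old/new
(position, bits, fitness) triples has lower fitness, so stored fitness
never increases.  Early iterations fall back to plain encircling /
search-for-prey while the pool holds fewer than the required members
(it gains one candidate per iteration); the fallbacks are logged.

The "binary conventional WOA" used as an ablation arm shares the
binarization and evaluation but keeps the classic dispatch (`|W| < 1`),
accepts moves unconditionally, and has no pool or migration.

## Wrapper fitness

A mask is scored `F = 0.99 (1 - accuracy) + 0.01 (n_selected/n_total)`:
classification error dominates, the size term breaks ties toward smaller
subsets.  Accuracy is that of a kNN classifier (k = 5, Euclidean,
min-max scaling fitted on training rows only) on a validation scheme
carved from the training split — a stratified 80/20 holdout by default,
or stratified k-fold averaging (`validation_scheme="kfold"`), which costs
k fits per evaluation but substantially reduces fitness noise and is what
the planted-recovery experiments use.  The final test split is never
touched during selection.  The all-zero mask is degenerate and scores the
supremum `F = 1` without fitting.

## Synthetic data

For a sample of class `c`:
`L_x = mu_c + sqrt(rho) z + sqrt(1-rho) e_x` (and analogously `L_y`),
`X_info = L_x A + noise`, with shared class centroids `mu_c ~
N(0, class_sep^2/latent_dim I)`, standard normal latents, unit-norm random
loadings `A, B`, and i.i.d. `N(0, noise_sd^2)` measurement noise.
Non-informative columns are independent standard normals.  Consequences:

* `view_correlation = rho` is the correlation of the *within-class*
  latent variation between views; the class-mean structure is always
  shared, since both views describe the same samples.  At `rho = 1`,
  `noise_sd = 0` and square loadings the informative blocks are exact
  linear images of the same latents and all sample canonical correlations
  are 1; at `rho = 0` the within-class cross-view correlation vanishes.
* With `latent_dim < n_informative` the informative columns are
  deliberately redundant (realistic for deep features, whose covariance
  is low-rank).  For planted-recovery experiments we set
  `latent_dim = n_informative` so that every informative column carries
  marginal class signal — otherwise the size term of the fitness
  *correctly* prunes redundant informative columns and "recover all
  informative bits" is not the optimum of the stated objective.

Defaults are the balanced four-class regime (1000/class; per-class counts
accept imbalance), 1280 columns per view, `noise_sd = 2.0`,
`view_correlation = 0.9`, `class_sep = 6.0`.  The separation/noise pair
was calibrated once, jointly: strong class structure in latent space
(`class_sep = 6`) measured through individually noisy columns
(`noise_sd = 2`).  This is the regime wrapper feature selection is for —
each informative column alone is weak (high measurement noise), but
their combination averages the noise out, so *every* informative column
contributes measurable accuracy and the wrapper-fitness optimum is the
full informative set.  Under milder noise a handful of columns saturate
the classifier (four classes span at most a rank-3 discriminative
subspace), and the size term of the fitness then makes pruning
informative columns the correct optimum — a degenerate planted problem.
At the desk-scale sizes used in the test suite (600 samples, 50 columns
per view, 10 informative each), a single raw view scores ≈ 0.7–0.75 with
5-NN and the Bartlett-truncated fused representation ≈ 0.9, leaving
visible headroom for each pipeline stage.  What the generator does *not*
emulate: heavy-tailed or
rectified (post-ReLU) feature distributions, feature-wise scale
heterogeneity, label noise, and class-conditional covariance differences.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative ordering of the pipeline arms, not clinical performance.

## Evaluation protocol

Stratified 80:20 train/test split (exact per-class proportions within
rounding); CCA fitted on training rows only; per-class TPR/FNR/PPV/FDR
from the confusion matrix with zero-denominator cells reported as NaN
(undefined) rather than 0; runs summarized as mean ± sample (n-1)
standard deviation; arms compared with a two-sided t-test — paired when
run counts match (runs share split seeds across arms), Welch otherwise.
Run-to-run variability comes from re-splitting and re-seeding the
optimizer together; the two seed streams are exposed separately in the
library API.

## Problem sizes in the test suite

Tests and the acceptance script run the generator at 600 samples
(4 x 150), 50 columns per view with 10 informative each (100 fused /
concatenated dimensions), bE-WOA with 20–30 whales and 60–150 iterations,
and 5-seed repetitions — sizes chosen so the full suite completes in
minutes on one CPU while every contract is exercised at full fidelity.

## Known limitations

* The bE-WOA keeps continuous positions as state and stochastically
  re-binarizes at each evaluation; fitness is therefore a noisy function
  of position, and reported best masks are the argmin over evaluated
  masks, not a deterministic function of the final positions.
* CCA fusion assumes the class signal is (partly) shared across views;
  with uncorrelated views the fused representation offers no advantage
  over concatenating raw features.
* kNN wrapper accuracy on small validation folds is granular
  (1/n_val); k-fold validation mitigates but does not remove this.
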