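# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Haze model and enhancement

Images are `H×W×3` floats in `[0,1]`; 8-bit conversion happens only at file
boundaries. The enhancement assumes the veiling-glare model
`I = J·T + A·(1−T)` and runs dehazing first (it restores the global dynamic
range), then per-channel top-hat/bottom-hat sharpening
(`F = clip(J + tophat(J) − bothat(J))`), which amplifies small bright and
dark structure. Both top- and bottom-hat use the canonical definitions
(image minus opening; closing minus image), so both are non-negative and
vanish on flat images.

Defaults follow standard dark-channel-prior practice: `patch_size = 15`,
`omega = 0.95` (keeps 5 % of the veil so skies/highlights don't tear),
`t0 = 0.1` (transmission floor guarding the division), `light_fraction =
0.001` (top 0.1 % of dark-channel pixels vote for `A`, floored at 1e−3 per
channel). The structuring element is a disk of radius 9 at 256 px, scaled
proportionally with the short image side (minimum 1). All neighborhood
operations use replicate padding. Degenerate cases are pinned down by
construction: a constant image equal to `A` is a fixed point of the whole
chain; `recover_radiance` is the exact algebraic inverse of the forward
model wherever `T ≥ t0` (exposed via `clip=False` for verification).

## Feature contract, toy extractor, augmentation

`FeatureMatrix` (N×K values, row labels, provenance-carrying column names)
is the unit passed between stages and round-trips through CSV with a
`label` first column, so externally computed embeddings can be dropped in.
The built-in toy extractor computes per-channel 4×4 grid means/stds plus an
8-bin histogram and projects them through a random matrix seeded from the
extractor's name and width — deterministic, training-free, and differently
named extractors give complementary views the way distinct CNN backbones
do. It is a real feature extractor in its own right (grid statistics are a
classical texture/color descriptor), just a deliberately small one.

Flip augmentation emits exactly four variants per image (original,
left-right, up-down, both), labels replicated. In the pipeline, augmentation
is applied **inside training folds only**: flip variants of a test image
never enter the training set, because evaluating against near-duplicates of
training data inflates every metric.

## Serial correlation fusion

Fusion concatenates the sources column-wise, pairs consecutive columns
(`(0,1), (2,3), ...`; an odd last column pairs with itself and, being
perfectly self-correlated, lands in the positive set), and computes the
two-variable Pearson coefficient across samples in its raw-moment form.
Constant columns get `r = 0` by convention. Pairs with `r > 0.5`
(configurable) put both their columns in the positive set, the rest in the
weak set; each non-empty set is scored by stratified cross-validated 1-NN
accuracy (Euclidean, seeded folds; the "fine" k-NN configuration), an empty
set scores 0, and ties prefer the positive set. Correlation is computed
across samples (columns as variables): rows are samples everywhere in this
package. Both members of a positive pair are kept — the partition is about
where the class signal concentrates, not about deduplication.

## ALO-MD wrapper selection

The search space is the unit box `[0,1]^d`; positions decode to subsets by
thresholding at 0.5, with an all-below-threshold position rescued to its
single largest coordinate so every candidate selects at least one feature.
The wrapper score (minimized) is
`alpha·(1 − cv_accuracy) + (1 − alpha)·n_selected/d` with `alpha = 0.99`:
accuracy dominates and sparsity only breaks near-ties. Scores are memoized
per decoded mask — the fitness is a deterministic function of the mask, so
caching changes nothing numerically.

The exploitation schedule sets the shrink ratio `I = 10^u·s/S` with
`u = 2, 4, 5, 6` once the run passes 10 %, 50 %, 75 % and 90 % of its
iterations (`I` floored at 1, so the interval never expands). Walk intervals
are recentered on the guiding antlion (width preserved, clipped to the unit
box); each ant averages a walk guided by a roulette-selected antlion with a
walk guided by the elite. Roulette weights are min-shifted fitnesses plus a
tiny epsilon, so all-equal populations select uniformly. Replacement is
strict (ties keep the incumbent antlion) and the elite is updated only on
strict improvement, giving a provably non-increasing elite trace.

The mean-deviation step is this package's diversification mechanism: after
each iteration, ants scoring worse than the population mean plus the mean
absolute deviation are re-seeded uniformly inside the current elite-centered
interval and re-scored. It never touches the elite, is toggleable
(`md_enabled=False`) for ablation, and in practice shortens the tail of
stagnating runs on the planted-feature fixtures.

Initial antlions are the best of the combined initial ant/antlion draws, so
no good starting point is lost before the first elite is chosen.

## GA hyperparameter search

Defaults: population 20, 30 generations, tournament size 2, uniform
crossover at 0.8, per-gene mutation at 0.1 (Gaussian with sigma = 10 % of
the range, in log10 space for log-scale parameters; resampling for
categoricals), elitism 2, bound clipping after every operator. A failing
fitness evaluation scores that chromosome as worst and the run continues.
The pipeline's GA stage tunes a degree-2 polynomial SVM's `C` and `gamma` by
stratified 70/30 hold-out accuracy on the fusion-chosen set; published fixed
values such as learning rate 0.001 or momentum 0.07 are treated as example
defaults of a declared space, not constraints.

## Evaluation harness

Stratified k-fold (default 10, degraded to the smallest class count, floor
2) with pooled out-of-fold predictions scored once. Macro averaging is the
headline convention — one rate per classifier row regardless of class count
— with micro variants included for transparency; classes absent from both
truth and prediction are excluded from macros with a warning. MCC uses the
covariance-form multiclass generalization from the confusion matrix; kappa
is `(po − pe)/(1 − pe)`; the Fowlkes–Mallows index is the geometric mean of
macro precision and macro sensitivity; FNR is exactly `1 −` macro
sensitivity. AUC is macro one-vs-rest on pooled class scores; classifiers
without probabilities contribute per-fold min-max-scaled decision values.
The classifier roster maps Classification Learner preset names to documented
scikit-learn configurations (e.g. quadratic SVM = degree-2 polynomial
kernel; weighted k-NN = distance-weighted k = 10; narrow/medium/bi-layered
NN = MLPs with (10,), (25,), (10,10) hidden units); the presets' exact
internals are proprietary, so every entry is overridable.

## Synthetic generators

**Images** (default 64×64, 7 classes, 30/class): a skin-toned background
with a soft-edged, class-colored elliptical blob plus Gaussian pixel noise
(sigma 0.01) forms the clean image; haze is then applied with the forward
model itself, using `T = exp(−β·depth)` over a smooth depth field with base
optical depth 0.5 rising radially to 1 (the base term models the veil
covering the whole field of view — that is what makes the hazy images
globally low-contrast) and atmospheric light 1.0. Because noise precedes
hazing, the forward model is exact: recovery with the true `A` and `T`
reproduces the clean image to floating precision, which the tests assert as
PSNR > 40 dB.

**Feature tables** (default 200×(5 informative + 40 noise + 5 redundant),
7 classes, separation 6): informative columns are unit-variance Gaussians
whose class means sit on binary codes scaled by the separation; the code
book starts with the zero vector and the unit vectors, so every informative
dimension is needed to distinguish at least one class pair whenever there
are more classes than informative dimensions — this makes "recover all
planted features" a well-posed target. With more classes than distinct
codes, classes share codes after a seeded permutation, modelling an
extractor that only resolves groups of classes; the pipeline's default
three sources use exactly this to make each source weak alone (~0.5
accuracy) and their fusion strong (>0.99). Redundant columns are informative
copies plus `N(0, 0.1²)` jitter (pairwise `r > 0.9`); the `paired` layout
interleaves them with their sources so they form consecutive fusion pairs.
Labels are balanced and deterministic (`i mod n_classes`), so tables from
different seeds align row-wise.

What passing these fixtures does **not** show: robustness to hair/ruler
artifacts, specular highlights, class imbalance, label noise, or the
covariance structure of real CNN embeddings. The fixtures verify the
machinery (inverse models, partitions, optimizer behavior, metric algebra),
not clinical performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale —
21-image enhancement batches, 80–210-sample tables, 20-seed repetitions,
exhaustive search limited to d ≤ 20 — chosen so the full loop completes in
well under a minute while leaving the measured rates far from their
thresholds. 1-NN predictions use an exact distance-matrix nearest-neighbor
(`k = 1`) and scikit-learn's KNeighborsClassifier for `k > 1`. All
randomness flows through `numpy.random.default_rng` seeds; every public
operation is deterministic given its seed arguments.

## Known limitations

- No guided-filter transmission refinement; the raw dark-channel
  transmission can halo around strong edges.
- The selection fitness assumes a k-NN wrapper; other wrapped classifiers
  plug in via `knn_fitness`-style callables but are not pre-wired.
- The image pipeline's augmented evaluation retrains once per fold on
  4× the training rows, which scales linearly in the augmentation factor.
- Lesion *localization* is out of scope; there is no segmentation stage.
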