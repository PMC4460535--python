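# Methods

`blockdecode` implements a complete multi-voxel pattern analysis (MVPA)
pipeline for block-design fMRI: a synthetic-session generator with planted
ground truth, hemodynamic deconvolution, fold-nested univariate voxel
selection, a feed-forward-network decoder with block-level decision rules,
temporal-unit cross-validation with permutation inference, and per-voxel
relevance mapping by network sensitivity analysis with recursive feature
elimination, alongside searchlight and GLM reference maps.

## The experimental design being modeled

A session consists of several 6-minute runs at TR = 2.5 s (144 frames per
run). Each run alternates 15-s "travel" epochs (no characters on screen,
count 0) with 15-s character epochs showing 1–6 characters; every count
appears exactly twice per run, as two concatenated random permutations of
1..6, giving 12 character blocks (72 character frames) interleaved with 12
travel blocks. Character type (soldier vs insurgent) is fixed within a run
and alternates across runs. The decoding target is the character count, a
balanced six-class problem with chance accuracy 1/6 ≈ 16.7%. The generator
fixes strict travel/character alternation starting with a travel block,
matching a camera that travels between presentation sites.

## Synthetic BOLD model

A chosen subset of voxels is informative: during a count-c block such a
voxel carries a neural amplitude `effect_scale * class_patterns[c-1, j]`,
zero during travel. Class patterns are drawn once per seed from a standard
normal (optionally as a random walk over the ordinal count axis, so
adjacent counts have more similar patterns and confusions concentrate just
off the diagonal). The neural boxcar is causally convolved with the
hemodynamic response kernel and truncated at run end. Noise is white
Gaussian innovations of standard deviation `white_sd` filtered by an AR(1)
recursion with coefficient `ar1_coeff` (defaults 1.0 and 0.4; at
coefficient 0 this is pure white noise). Uninformative voxels carry noise
only. All draws flow from named substreams of one root seed, so identical
(arguments, seed) give bit-identical data.

What the generator deliberately omits: spatial structure (no smoothness,
no anatomical layout), scanner drift and spikes, motion, physiological
nuisance, and any location or character-type signal — class is the only
signal driver. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated temporal/statistical model,
not performance on real brains.

## Preprocessing

The first 15 s of each run are discarded (transient suppression; event
onsets are shifted accordingly). Each voxel's series is then deconvolved
with a Wiener filter, `X(f) = conj(H(f)) Y(f) / (|H|² + nsr)`, using a
difference-of-gamma kernel: gamma densities with shape `delay/dispersion`
and scale `dispersion`, peak time ≈ 5 s with canonical parameters
(delay₁ = 6 s, delay₂ = 16 s, dispersions 0.9 s, undershoot ratio 0.35),
peak-normalized to 1. The noise-to-signal ratio is a scalar regularizer
(default 0.02) rather than a frequency-dependent spectrum — the standard
reduction when no noise model is available. Signals are zero-padded to the
next power of two ≥ 2× their length to avoid circular wrap-around; series
are mean-centered before filtering and the mean restored after, keeping DC
behavior predictable. At nsr = 0 the filter inverts convolution exactly
(verified to < 1e−6). Deconvolution mainly re-aligns the response peak
with its stimulus block.

## Feature selection

One-way ANOVA per voxel, in two modes: `task_activated` (characters
present vs travel, binary) or `classification_target` (the six counts;
the default, and empirically the better mode for count decoding).  Voxels
are ranked by F (ties broken by ascending index) and the top k kept
(default 2000 for full-scale volumes; tests use much smaller k). Ranking
by F rather than a significance cutoff reflects that a voxel *count* is
the quantity of interest. Selection is always re-run inside each
cross-validation fold on training rows only; the fold driver enforces
train/test disjointness.

## The decoder

One hidden layer, tanh hidden units, per-unit logistic outputs. The
single-hidden-layer, per-unit-output architecture is load-bearing: the
sensitivity analysis needs diagonal activation-derivative matrices, which
rules out softmax coupling across outputs. Raw outputs approximate class
posteriors; they are clipped at 0 and normalized to sum to one (uniform
fallback if all ≤ 0), the argmax is the label (ties to the lowest class),
and the normalized output of the chosen label is its *confidence*.

Training minimizes mean squared error against one-hot targets using
L-BFGS on the closed-form backprop gradient (max 500 iterations), with
early stopping when a block-stratified validation split (fraction 0.25)
stops improving for 25 iterations. Inputs are standardized per feature
with training-fold statistics. Model selection is two-phase: a grid
search over hidden sizes (default {4, 8, 16, 32, 64}; ties prefer fewer
units), then 20 restarts at the chosen size keeping the best validation
accuracy — the restart phase measurably reduces the variance of the
returned net. Validation is split at *block* granularity to avoid
temporal leakage between fit and validation frames of one block.
Baselines behind the same adapter surface: one-vs-one linear SVM (C = 1),
Gaussian naive Bayes, and k-nearest neighbors (k = 6), via scikit-learn.

## Block integration

Four rules pool per-frame information over a block: input averaging
(average the frames, classify once), block voting (majority of frame
labels), confidence voting (frame votes weighted by confidence,
`argmax_c Σᵢ wᵢ·1_c(cᵢ)`), and output averaging (argmax of the per-class
posterior sums). Block voting is implemented as the literal majority; a
median variant (round-half-down on sorted ordinal labels) is available
because majority and median can differ on bimodal blocks such as
[1,1,1,4,4,4]. Tie hierarchy: greater summed confidence when posteriors
are available, else the smallest label — deterministic by construction.

## Cross-validation and inference

Frames are grouped into temporal units of 1 (frame), 6 (block), 36
(half-run), or 72 (run) consecutive character frames, never spanning
runs; folds are drawn over whole units (stratified by unit label where
possible, resampled a bounded number of times if a class is missing from
a training fold). Defaults: 10 folds for frame/block, 8 for half-run, 4
for run splits. Because the hemodynamic response correlates nearby
frames, frame splits are optimistically biased; block split is the
recommended operating point.

Significance: labels are permuted across selection units (keeping a
unit's frames together, which preserves within-unit correlation under the
permuted null), the full pipeline re-run, and the add-one p-value
`(1 + #{perm ≥ obs}) / (1 + n_perm)` reported (default 2000
permutations). Uncertainty: percentile bootstrap of the mean (default 68%
intervals, 2000 resamples). Confusion matrices are row-normalized to
percentages with empty rows flagged.

## Sensitivity mapping and recursive feature elimination

For input x, the Jacobian of outputs w.r.t. (standardized) inputs is
`S(x) = O′ · W · Y′ · V` with diagonal derivative matrices evaluated on
the forward pass — verified against central finite differences to 1e−5.
Because training is stochastic, S is averaged over an ensemble of
independently trained nets (100 for final maps), RMS-averaged entrywise
over all character-frame input vectors, and reduced to a per-voxel
relevance `φᵢ = max_k S_RMS[k,i]`. Sensitivities live in
standardized-input space so φ is comparable across voxels.

RFE iterates: train an ensemble on the surviving voxels, compute φ,
remove every voxel with φ strictly below a fixed threshold (default: the
10th percentile of the initial φ distribution; at least one voxel per
iteration to guarantee progress), and re-estimate accuracy by
cross-validation. The elimination path keeps one fixed fold partition so
successive estimates are paired and iteration-to-iteration change
reflects the feature set, not fold redraws. Bootstrap draws are taken
over fold accuracies — the fold is the replication unit of the estimate;
per-decision resampling ignores fold-assignment variance and makes the
stop rule trigger-happy. Iteration stops when a one-sided bootstrap
comparison puts current accuracy below the running peak at p < 0.05 on
two consecutive iterations (a single significant dip can be a training
fluke), when one voxel remains, or at the iteration cap. RFE ensembles
default to 20 nets (vs 100 for final maps) for tractability; both are
configurable.

Reference maps: a searchlight (3×3×3 kernel truncated at volume/mask
boundaries, linear SVM, cross-validated accuracy per center voxel,
threshold 2× chance = 33%) and a per-voxel OLS GLM with one explanatory
variable per character count, mapped as the largest |t| across count
regressors (no cluster correction — surface projection and cluster
inference are out of scope). Percent coverage summarizes a thresholded
map as the fraction of supra-threshold voxels in each label of an
anatomical partition (unlabeled voxels count as "other"; fractions sum to
one). No per-voxel p-values are attached to sensitivity maps; there is no
practical calibration for them, so thresholded maps are for qualitative
comparison.

## Contrast confound control

Per-frame RMS contrast is sd(luminance)/mean(luminance). The synthetic
contrast series is `base + slope·count + jitter`, with jitter drawn once
per frame position. The control GLM uses one indicator regressor per
count with no global intercept (so each coefficient is that count's mean
contrast) and t-tests each coefficient against the grand mean, two-sided;
the intercept-plus-covariate parameterization is available via the
Pearson correlation between contrast and count that is reported alongside
(count > 0 frames only). The contrast-only classifier control trains on
the single contrast feature with a two-fold design split: within each run
the first six character blocks (one complete permutation of 1..6) form
one fold and the last six the other, the only two folds that are unique
and contain every count, regardless of run count.

## Problem sizes used by the test and acceptance suites

Stochastic properties are measured on scaled synthetic sessions chosen so
each effect is well inside its detectable regime: split-bias and chance
calibration use 2-run sessions, 60 voxels (10 informative), effect 0.7,
white sd 1.2, AR(1) 0.6, linear SVM, 20 seeds; block integration uses
effect 1.4, white sd 1.0, AR(1) 0.4 with the network decoder (hidden size
8, 2 restarts), 20 seeds; RFE uses 3-run sessions with 10 informative
voxels among 200, effect 2.5, 4-net ensembles, 6 folds, 20 seeds;
permutation calibration uses pure-noise 2-run sessions with Gaussian
naive Bayes at 19 permutations × 200 replicates, and bootstrap coverage
uses Gaussian samples of size 10 × 500 replicates. These are the
package's reference conditions; larger sessions only sharpen the same
effects.

## Known limitations

- The generator's noise model is temporal only; no spatial correlation,
  so searchlight and coverage behavior on real, spatially smooth data is
  not exercised.
- The permutation null permutes at selection-unit granularity; a
  frame-level permutation under coarser splits would break exchangeability
  and is deliberately not offered.
- MSE-on-logistic training can underperform in very low signal-to-noise
  regimes where margin-based classifiers still find structure; the
  decoder is intended for the well-above-chance regime.
- The RFE stopping threshold and removal percentile are heuristics; the
  trajectory (not just the stopping point) is the primary output.
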