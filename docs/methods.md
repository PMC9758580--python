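# Methods

`replaysim` simulates the consolidation of category knowledge by offline
replay in a layered convolutional classifier. A network learns image
categories across "days" (one training epoch on real, augmented images per
day) and consolidates across "nights" (training on replayed activation
patterns injected at an intermediate layer). This note records the model,
the synthetic task, the parameter choices that matter, and the limits of
what the desk-scale simulations can show.

## The classifier and its cut points

The classifier is a VGG-style stack: five blocks of 3×3 same-padded ReLU
convolutions, each closed by a single 2×2 max-pool, followed by two fully
connected layers (each with dropout 0.5) and a softmax output. The pooling
layer ending block *k* is the named cut point `pool_k`; cut points are the
only places where the network may be truncated and replay injected,
mirroring stages of the ventral visual stream (early cuts ≈ early visual
cortex; `pool_4` ≈ lateral occipital cortex).

Two presets share this topology:

* `vgg16` — the full-scale architecture (blocks of 2×64, 2×128, 3×256,
  3×512, 3×512 convolutions; 4096/4096 head). With 1,000 outputs it has
  exactly 138,357,544 trainable parameters, which the test suite checks by
  summing materialized weight arrays.
* `mini` (default) — 64×64×3 input, blocks of 1×8, 1×16, 1×32, 2×64, 2×64
  convolutions and a 128/128 head (≈186k parameters). It preserves the
  five-block/five-cut topology at a size where CPU experiments take
  minutes.

Everything is NumPy: im2col convolutions, hand-written backpropagation
(gradient-checked against central differences), float32 arithmetic, and
Adam (learning rate 3 × 10⁻⁴, batch size 36, categorical cross-entropy —
the reference training configuration). The final partial batch of an epoch
is kept. Dropout and augmentation are disabled during every evaluation, so
evaluation is deterministic given the weights.

Before learning the task classes, each model replicate's convolutional base
is pretrained on a disjoint synthetic class set (default 12 epochs on 20
classes × 64 images), standing in for the "experienced network" premise:
new categories are learned by fine-tuning a visual system that already
works. The fully connected head is always freshly initialized
(variance-scaling uniform) from the replicate's seed, and all parameters
remain trainable.

## Synthetic image categories

Categories are procedurally rendered 64×64 RGB texture compositions. A
`CategoryPrototype` fixes twelve feature parameters: the mean orientation
and base frequency of a primary grating, the relative angle of a second
grating, a stripe-sharpness exponent, a mixing weight, a contrast
amplitude, a weak color tint, occluder-blob count/size tendencies, and a
background brightness. Rendering an image jitters the class parameters,
draws a random background (brightness, color cast, gradient), random
grating phases, and random occluding blobs, then adds pixel noise. The
`difficulty` parameter of a prototype scales all within-class jitters and
the pixel noise monotonically.

Two design constraints matter, and both were learned the hard way:

* **Class identity must not live in low-level statistics.** If classes
  differ in palette or background, the class-conditional Gaussians fitted
  at the *earliest* cut are already highly informative and replay there
  works as well as at late cuts — the opposite of what happens with natural
  image categories, where early-layer features are generic. Backgrounds,
  blob positions/colors and grating phases are therefore drawn per render;
  discriminative structure only emerges at intermediate spatial scales.
* **Class identity must survive the augmentation pipeline.** Training
  images are augmented each epoch (rotation up to 20°, shifts and zoom up
  to 20%, horizontal flips, reflection fill — the reference augmentation
  set). Classes defined purely by absolute orientation are scrambled by
  the rotation augmentation, which devalues real-image days relative to
  replay; classes defined purely by augmentation-invariant relations
  (relative angle, frequency ratio) are learnable but slowly. The default
  classes therefore combine a wide-spread absolute orientation (within-class
  spread comparable to the rotation range), an absolute base frequency, the
  relative grating angle, and stripe sharpness.

The default split is 234/26/10 images per class (the canonical
117 : 13 : 5 train/validation/test ratio divided by five); the canned
studies use 72/8/20 per class so that a five-condition, five-replicate
study runs in minutes on one CPU (the larger test split reduces evaluation
noise at negligible cost). A `grouped` similarity mode draws all classes as
small offsets of one base prototype, for experiments on conceptually
similar categories; `difficulty_profile` assigns per-class difficulty for
the rebalancing experiment.

`augment_image` is the per-image reference implementation (bilinear
interpolation about the image center, reflection fill via
`scipy.ndimage.affine_transform`); `augment_batch` is a vectorized
equivalent used in the training loop, which agrees with the reference to
interpolation tolerance. Transform parameters are drawn uniformly within
the configured bounds, one draw per image per epoch. Preprocessing
subtracts the training-split channel means (a stand-in for full-scale mean
subtraction; the exact color convention is irrelevant for synthetic data).

## Replay

Each night, the activations that the day's training images induced at the
chosen cut point are captured — from exactly the augmented views the
network processed that day — and, per class, spatially downsampled by
block-mean pooling (default factors 8, 4, 4, 2, 1 for `pool_1`..`pool_5`;
the text the schedule derives from is ambiguous between {8,4,4,2} and
{8,4,3,2} for the first four cuts, so the factors are fully
config-exposed). One multivariate normal per class is fitted over the
flattened maps (sample mean and covariance plus a diagonal jitter of 10⁻⁶
× the mean diagonal entry, since the covariance is singular whenever the
dimension exceeds the per-class image count). Sampling draws novel
"imagined" patterns from the Gaussian, reshapes and upsamples them
(nearest-neighbour) back to the cut layer's resolution. Samples are not
clipped to be nonnegative by default (an optional flag exists), staying
with plain Gaussian sampling. Each distribution is factorized once per
night (Cholesky, eigenvalue-clipping fallback), so *n* draws cost one
factorization plus *n* matrix-vector products.

The night itself truncates the network at the cut and trains only the
layers above it for one epoch on the pooled, shuffled replay samples with
their class labels (same optimizer settings as day training; a fresh Adam
state per night, mirroring the nightly disconnect/reattach). The truncated
head shares weight storage with the parent model, so consolidation
persists when training on real images resumes; weights at or before the
cut are untouched by construction. Per night, the number of generative
samples per class equals the per-class training count, keeping day and
night exposure matched.

Variants:

* **Veridical replay** trains on the exact captured activations
  (undownsampled) instead of Gaussian samples.
* **Continuous replay** has a single real-image day; distributions are
  fitted once from that day and every later day-night cycle is two replay
  epochs (the day-slot and the night-slot) with fresh samples, and no real
  images. Test accuracy is recorded once per cycle.

## The replay scheduler

The scheduler is a linear value network with one input per class, no bias,
and a single output: the predicted value of replaying that class. Classes
are selected probabilistically through a softmax over the values; the
selected class contributes one generative batch of 36, which is trained
through the truncated network; the main network is then re-evaluated on
the validation split, and the scheduler's reward is the *reduction* of the
chi-square gap Σ_c (total_c − correct_c)² / total_c — the Pearson distance
between perfect per-class prediction and the observed correct counts (a
pooled single-cell variant is available behind a flag). The side network
is fitted to the latest (one-hot, reward) pair for 50 Adam steps at
learning rate 10⁻³ (mean-squared error); with a one-hot input and no bias
only the chosen class's value moves. Initial values come from replaying
one batch of each class in turn and measuring the reward. Per night the
scheduler takes ⌈f·C·n_train/36⌉ steps; the factor f defaults to 1
(exposure parity with the generative condition) and the rebalancing study
uses f = 2. Validation activations at the cut are computed once per night
since upstream weights are frozen while the network is truncated.

Three desk-scale calibrations, all recorded here because the design was
genuinely open:

* **Persistent head optimizer.** Scheduled replay reuses one truncated
  head (and its Adam state) across nights, as day training reuses its
  optimizer across epochs. With a fresh optimizer every night, the last
  few single-class batches of a night dominate the head at this scale and
  whole classes flip between 0 and 100% accuracy.
* **Selection temperature.** Rewards are raw chi-square differences, whose
  scale grows with the validation count; at desk scale a unit-temperature
  softmax saturates and a single class monopolizes replay. The scheduler
  exposes the temperature (default 1); the rebalancing study sets it to 4
  (about half the per-class validation count), which keeps selection
  between monopoly and uniformity.
* **Interaction count.** The scheduler learns from two orders of magnitude
  fewer (selection, reward) interactions per study than at full scale. The
  rebalancing study therefore doubles the per-night scheduler step count
  relative to exposure parity; curve comparisons between conditions keep
  parity.

## Protocols, metrics and the canned studies

`run_condition` executes one condition (`none`, `generative`, `veridical`,
`continuous`, `rl_generative`) over independently seeded replicates; a
single master seed deterministically spawns separate streams for weight
initialization, training order/augmentation/dropout, replay sampling, and
scheduler selection, so any replicate's trajectory depends only on
(master_seed, replicate). Test accuracy is recorded at day 0 (untrained,
for chance-level checks) and after every day-night cycle; in the scheduler
condition, per-class accuracy is additionally recorded after the first day
but before any replay (the "originally learned" baseline).

Derived metrics: relative day-over-day improvement r_n = (a_{n+1} − a_n) /
(1 − a_n) (NaN where a_n = 1); relative increase from baseline
(a_replay − a_base)/a_base; OLS of per-class selection counts on baseline
per-class accuracy (slope, intercept, R², with NaN markers for a constant
predictor); condition × day mean ± s.e.m. tables over replicates.

The canned studies fix the desk scale: 10 classes, 64×64 images, 72/8/20
splits, mini preset, 12×20-class pretraining, 10 days, 5 replicates, with
pretrained bases shared across the conditions of a comparison (paired
comparisons). `phenomenon_suite` runs no-replay, generative replay at
`pool_4` and `pool_1`, veridical, and continuous replay.
`rebalancing_study` runs scheduler-driven replay on classes with a linear
difficulty gradient from 0.15 to 0.55 — wide enough to spread early
accuracy, mild enough that every class is learnable within ten days — and
reports per-replicate selection-count regressions and the across-class
accuracy spread before (day 1, pre-replay) and after scheduled replay.

## What the synthetic task does and does not show

The generator reproduces the statistical *structure* the analysis needs —
prototype-plus-variability categories, class information concentrated at
intermediate scales, tunable similarity and difficulty — not the content
or scale of natural image collections. Passing studies therefore
demonstrate that the pipeline reproduces the qualitative phenomena in a
regime engineered to be analogous: generative replay at a late cut
accelerates generalization over no replay and over the earliest cut;
imagined and veridical replay are comparably effective; continuous replay
from a one-day snapshot improves strongly over its first day but stays
below interleaved learning and replay; and replay's relative benefit
concentrates in early days. Absolute accuracies are not comparable to
full-scale results.

Known limitations, all consequences of the ~50× reduction in optimizer
steps relative to the full-scale setting:

* The margin separating continuous from interleaved generative replay
  exists here because a moderately pretrained base still *drifts* during
  the ten days, improving the nightly refits; with a fully converged base
  the frozen day-1 distributions are nearly as good as refit ones and the
  margin closes.
* The rebalancing tendency of the scheduler (weakly learned classes
  selected more) is reliable at the canned study's seeds but can invert
  for unlucky early-training transients, where replaying already-claimed
  classes reduces chi-square more than replaying unclaimed ones; the
  full-scale setting averages over ~50× more scheduler interactions per
  study.
* Single-class replay batches are a substantial fraction of a desk-scale
  epoch, so scheduler-driven runs are noisier than uniform generative
  replay; the two are not exposure-for-exposure identical in effect, only
  in volume.

Numerical conventions: float32 network arithmetic with float64 statistics
(covariances, schedulers, metrics); covariance jitter as above; max-pool
backward routes gradient to all window maxima (exact ties occur only at
zero, where the preceding ReLU already blocks gradient); softmax computed
with max-subtraction; evaluation batched at 64 images. Degenerate inputs
(empty splits, unknown cut points, non-PSD covariances after
regularization, non-finite rewards) raise informative errors rather than
propagating NaNs.
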