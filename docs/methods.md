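# Methods

This note documents the models, the synthetic data generator, the numerical
conventions, and the design choices behind `fundusvqa`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The bi-level VQA system

A multi-level VQA system is a sequence of levels; every level before the
last predicts a *routing key* that a switch function uses to forward the
(image, question) pair, and the last level predicts the answer. The
implementation supports the general n-level loop, but only the bi-level
instantiation is exercised: level 1 is a single question-type classifier
over {whole, region, fovea, grade}; level 2 is a set of answer models over
the global five-way answer space {yes, no, grade 0, grade 1, grade 2}.

Key semantics:

* **Single global answer space.** Every level-2 model has a 5-way head.
  Specialization comes from routing, not from restricting label spaces:
  each model is trained on *all* data and simply happens to be better at
  some question types.
* **Intermediate predictions are switch-internal.** The level-1 type
  prediction is consumed only by the switch; it is never passed to the
  level-2 model, and a misclassified type is routed per the (wrong)
  prediction, not corrected. The assembly's reported accuracy therefore
  includes level-1 errors.
* **Routing tables** map each type to the level-2 model with the highest
  per-type validation accuracy (ties: earlier model). With a perfect
  router and routing derived on the evaluation set itself, the assembly's
  overall accuracy is the support-weighted per-type maximum, which is ≥
  every single component's overall accuracy — the mechanism the bi-level
  design exists to exploit. With a learned router and routing derived on a
  finite validation set, the inequality holds in expectation but an
  individual run can lose it to estimation noise; the end-to-end check is
  therefore framed over a majority of three seeds.

## 2. Component models

The reference encoders are deliberately small, trainable-from-scratch
stand-ins that honor the interface contracts of large pretrained backbones
(a discriminator-style text encoder consumed via its `[CLS]` state; a
patchify-embed-attend-pool image encoder). An adapter seam — the
`extract_text_features` / `extract_image_features` signatures — lets a
pretrained backbone replace either branch without touching the rest of the
system. Replaced-token-detection pretraining and shifted-window attention
are out of scope; the pooled-feature contract is what is implemented.

Defaults (all configurable through `EncoderConfig`): feature widths
D_t = D_v = 64, two single-head post-norm attention blocks per branch,
patch size P = 8, MLP ratio 2, head hidden width 128, maximum question
length 12 tokens. The tokenizer is word-level (lowercase,
punctuation-stripped) with a vocabulary built from the training manifest —
adequate because the question language is a tiny closed template set.
Padding tokens participate in attention unmasked; with a fixed pad length
this is deterministic and the head learns around the constant
contribution.

Fusion L2-normalizes each modality vector independently (putting the two
modalities "on a similar scale"), concatenates text-first, and classifies
with a one-hidden-layer MLP; per-vector standardization is available as a
config switch. Argmax ties break toward the lowest label index.

Image normalization constants μ, σ are the per-channel mean/SD of the
training split, stored in every checkpoint.

## 3. Training and checkpoints

Cross-entropy with decoupled-weight-decay Adam. Defaults follow the
experiment-scale settings: batch size 32 (or 16), learning rate 1e-4,
weight decay 0.01. The alternative configuration (lr 1e-3, weight decay
0.9) is reachable through `TrainConfig`; a decoupled weight decay of 0.9
is implausibly aggressive for routine use, which is why 0.01 is the
default. Because the reference encoders start from random initialization
rather than pretrained weights, the fixture-scale experiments in the test
suite and acceptance script use lr 3e-3 — at 1e-4 the small models barely
move within a few epochs.

Validation accuracy is measured after ⌊steps_per_epoch/2⌋ optimizer steps
("half") and at the end of each epoch ("end"); a checkpoint (full
parameter copy, measured accuracy, provenance: epoch, phase,
hyperparameters, seed) is emitted at each point. All randomness —
initialization, shuffling — derives from the configured seed, and reruns
are bit-identical. Class weighting for the rare grade answers exists as a
flag but is off by default, matching plain cross-entropy training.

## 4. Greedy soup

Checkpoints are sorted by descending validation accuracy (ties keep
training order) and pre-filtered to the top k = 3. The soup starts from
the best checkpoint; each remaining candidate is tentatively averaged in —
a uniform mean over the would-be ingredient set, re-averaged from scratch
rather than maintained incrementally, which is numerically equivalent and
easier to audit — and kept iff the averaged model's validation accuracy is
**≥** the current soup's. The ≥ rule is the formal statement of the
algorithm; a strict-> variant exists behind `rule="strict"` because the
surrounding prose describes a strict inclusion condition. Averaging spans
all three components Θ₁, Θ₂, Θ₃ jointly; two parameter sets are combinable
only when their name sets and shapes agree exactly. Candidate evaluation
re-runs the full validation pass with no caching. Consequences asserted on
every run: the audit's accuracy sequence is non-decreasing, and the final
soup is never below its best single ingredient on validation.

## 5. The synthetic data generator

The generator emulates the *structure* of a DME-style fundus VQA dataset,
not its photometric realism. A latent scene holds: a retina disc on a dark
background; an optic disc (a bright Gaussian blob — a deliberate
distractor for lesion detection); a fovea rendered as a shallow dark dip,
with a single center and two radii (the fovea radius for fovea questions,
the larger macula radius for the grading rule); and zero or more
hard-exudate lesions (small bright Gaussian blobs). Multiplicative
illumination gain and additive Gaussian noise emulate acquisition
variability; noise is seeded per-scene so rendering is deterministic.

Answers are *always derived from geometry*: whole = any lesion exists;
region = any rasterized lesion disk overlaps the mask by ≥ 1 pixel
(continuous-geometry intersection is not used because a pixel-level
dataset cannot encode it); fovea = overlap with the fovea disk;
grade = 0 with no lesions, 2 on macula-disk overlap, else 1. Region masks
are disks clipped to the retina; the open question of real region-mask
shapes is resolved permissively — the manifest accepts any binary mask.

Per-answer balance is reached by bounded rejection sampling (≤ 50
attempts per slot) over *guided* proposals: the proposal may bias lesion
count or placement toward the target answer (e.g. place one lesion inside
the fovea for a fovea-yes target), but the stored answer is still the
derived one, and a proposal that misses its target is rejected. A guide
never widens the support of an explicitly fixed lesion-count
distribution, so impossible targets fail loudly with the offending
(split, type, answer) cell named.

Defaults: 96×96 grayscale images (small enough that CPU training takes
seconds per epoch; configurable upward); Poisson(2) lesion counts; lesion
radii 0.08–0.18 of the retina radius with intensities 0.75–0.95 and noise
SD 0.005–0.02, chosen so a lesion spans at least a few pixels at the
default resolution — a lesion below the raster's resolvable scale would
make the detection tasks vacuous. The `dme-like` preset reproduces the
DME split structure: a region-dominated train split (region ≈ 86.9% of
questions), a ~70%-region test split, equal shares of the three other
types, near-balanced yes/no answers, and grade answers imbalanced toward
grades 0 and 2 (0.389 / 0.096 / 0.515).

What the generator does **not** model: real fundus texture, vessels,
microaneurysms/hemorrhages, inter-image style variation, annotation
noise. Passing tests therefore demonstrate that the *machinery* —
routing, souping, evaluation, determinism — behaves correctly and that
the question semantics are learnable from pixels; they do not certify
clinical-scale accuracy on real fundus photographs.

For model input, a region sample's image is multiplied by a soft mask
(pixels outside the region dimmed to 0.25) so the questioned region is
delineated while global context is retained — the analogue of pairing a
region question with its mask.

## 6. Metrics

Per-class precision/recall/F1 are one-vs-rest with explicit 0/0
conventions (no predicted positives → precision 0; no true positives →
recall 0; P = R = 0 → F1 0). Macro aggregates are unweighted means of the
per-class values and weighted aggregates are support-weighted means —
the resolution under which the published aggregate rows follow exactly
from their per-class rows. Weighted recall equals overall accuracy for
every single-label confusion matrix; the report asserts this identity on
every evaluation. Internals stay at full precision; serialization rounds
proportions to 4 decimals and percentages to 2.

The seed study reports mean, sample SD (n−1), and a one-sample two-tailed
t-test against a fixed baseline — the exact reduction of a paired test
against a constant: t = (mean − baseline)/(SD/√n) with n−1 degrees of
freedom. SD = 0 is reported as an explicit degenerate flag rather than an
infinite statistic.

## 7. Problem sizes and numerical conventions

* All floating-point math is float64, on a small reverse-mode autodiff
  engine written for this package and verified against central finite
  differences in the test suite.
* Softmax/log-softmax subtract a detached rowwise max for stability;
  layer norm uses ε = 1e-5; L2 normalization uses ε = 1e-12 so the zero
  vector maps to zero (flagged in logs at the public `fuse` surface).
* The acceptance experiment runs the dme-like preset at 2,000 samples
  (1,400/300/300) and 96×96 pixels with 32-wide single-block encoders,
  repeated over three derived seeds; the in-suite end-to-end test uses
  500/150/150 at 48×48. These scales keep the full pipeline in the
  minutes range on one CPU while leaving the routing mechanism
  measurable.
* The three level-2 models differ in *design* (patch sizes 8/12/16 at
  96×96, i.e. different spatial resolutions) as well as batch size and
  epochs. Hyperparameter-only variation at this scale produced components
  too similar for routing to separate — per-type differences were noise —
  whereas resolution diversity yields genuine per-type specialization,
  which is what the second level of a bi-level system is supposed to
  contain.
* Checkpoint archives are zip containers of `.npy` entries plus a JSON
  metadata block, written with fixed timestamps so identical content is
  byte-identical. Manifests are JSON-lines; images and masks are 8-bit
  PNG (masks strictly 0/255 on disk, {0,1} in memory); predictions are
  CSV; reports and audits are JSON. Every artifact embeds the config hash
  and seed that produced it.

## 8. Known limitations

* The fovea question is the hardest synthetic task (it requires
  localizing a small lesion relative to a rendered landmark); small
  reference encoders learn it only partially. This mirrors the real
  task's difficulty ordering but at lower absolute accuracy.
* Level-1 accuracy is near-ceiling because the four question templates
  are text-separable — faithful to the original task, but it means the
  router contributes little error diversity at fixture scale.
* The generator's geometry and the learned models share no nuisance
  factors beyond illumination/noise; domain shift, co-registration error,
  and annotation disagreement are absent by construction.
* A paired t-test against a constant baseline cannot model correlation
  between runs; it is reported because it is the analysis the seed table
  calls for, with its degenerate case handled explicitly.
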