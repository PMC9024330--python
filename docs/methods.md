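# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical conventions, and what the synthetic
data does and does not establish.

## Multi-rater fusion

### Binary STAPLE

Raters produce binary decisions D_ij ∈ {0,1} for pixel i. The model
assumes, conditional on the true label T_i, that raters err independently
with per-rater sensitivity p_j = P(D_ij=1 | T_i=1) and specificity
q_j = P(D_ij=0 | T_i=0), and that pixels are independent given the
rater parameters (no spatial coupling). EM alternates the posterior
W_i = P(T_i=1 | D, p, q) with re-estimation of (p_j, q_j) from the
W-weighted counts. Products over raters are computed in log space.

Numerical conventions:

- **Prior** g: spatially uniform, set to the mean foreground fraction
  across raters (scalar or per-pixel fields are also accepted). The
  data-driven prior avoids a degenerate fixed 0.5 on unbalanced classes
  and matches the convention of the common ITK implementation, which the
  test suite uses as an independent reference (agreement within 1e-4 on
  small grids).
- **Initialization** p = q = 0.99999; parameter estimates are clipped to
  [1e-12, 1−1e-12] each M-step for stability.
- **Convergence**: max per-pixel |ΔW| < 1e-6, at most 100 iterations (both
  configurable). The observed-data log-likelihood Σ_i log(a_i+b_i) is
  recorded every iteration; tests assert it never decreases.
- **Degenerate input**: all-empty masks with a zero prior return an
  all-zero W, flagged rather than raised, since it arises naturally for
  classes absent from an image.

### Multi-class extension

One binary STAPLE per class (one-vs-rest over {benign, 3, 4, 5}), stacked
and normalized per pixel, then argmax. This is deliberately *not* a joint
multinomial STAPLE: the per-class posterior picture followed by a
multi-category argmax keeps each sub-problem a standard binary EM and lets
classes with different prevalences carry their own priors. Pixels whose
maximum posterior is attained by more than one class (compared with
tolerance 1e-9 — exact float equality is brittle) are recorded as ties and
resolved by seniority: the most experienced rater who annotated the image
supplies the label; if that rater is absent (per-image missingness) or
marked the pixel non-tissue, the ranking is descended to the first present
rater. The majority-vote baseline uses the identical tie rule, so the two
fusers differ only in their weighting of raters.

Non-tissue pixels (label 255) carry no annotation signal: pixels that
every rater marks 255 are excluded from the EM and copied through; a
single rater's 255 at a tissue pixel counts as a background vote in each
one-vs-rest problem.

Known limitation: the conditional-independence assumption is violated when
raters share systematic biases (e.g. a common training tradition); STAPLE
then over-trusts the correlated majority. The simulation draws rater
errors independently, so this failure mode is not exercised.

## Synthetic TMA cores

The generator exists so that fusion, training, evaluation and grading are
all testable against known truth. It emulates:

- a roughly circular tissue disc (radial low-order wobble) on an empty
  background, non-tissue marked 255;
- class regions as Voronoi cells of random centres, assigned greedily to
  match requested area fractions (realized fractions track targets to
  within cell granularity; leftover area becomes benign);
- per-grade texture: pale open stroma (benign), ring-like well-formed
  glands with white lumens (pattern 3), fused poorly-formed gland blobs
  without lumens (pattern 4), near-solid dark sheets (pattern 5). The
  palettes are deliberately well separated in colour so that a tiny,
  CPU-trainable network can genuinely learn class appearance;
- raters with known row-stochastic confusion matrices (off-diagonal mass
  tilted toward morphologically adjacent patterns), bounded smooth
  boundary jitter (labels resampled through a random displacement field of
  max magnitude `boundary_jitter_px`), and per-image coverage draws. The
  default panel of six has diagonals 0.97…0.85 ranked by seniority, 2 px
  jitter, and coverages (1, 1, 1, 1, 0.85, 0.41) — four complete raters
  and two partial ones at roughly 85% and 41% of images, mirroring a
  multi-expert challenge setting.

What passing tests on this data do **not** show: robustness to stain
variation, scanner artefacts, correlated rater bias, or gland morphology
at realistic ambiguity — the palettes make classes far more separable
than real H&E. The synthetic results validate the *machinery*
(estimators, losses, rules, reproducibility), not clinical performance.

## Segmentation network

Layout: residual backbone → pyramid pooling module (PPM) → main head,
with an auxiliary head on the penultimate backbone stage during training.

- **PPM**: average pooling on 1×1, 2×2, 3×3 and 6×6 grids (cell edges at
  floor/ceil of i·H/b, so non-divisible sizes are fine), a 1×1
  convolution per branch, bilinear upsampling back to the feature size,
  concatenation with the input map. Branch width defaults to C/4 so the
  module doubles the channel count. The bin-1 branch reduces to broadcast
  global average pooling, asserted in tests.
- **Bilinear convention**: corner-aligned, pinned in the config because it
  affects bit-level outputs.
- **Composite loss**: L = L1 + α·L2 with α = 0.5; both terms are per-pixel
  cross-entropies, label 255 excluded, no class weighting. Both losses
  backpropagate through all convolution layers; only the main head is used
  at inference.
- **Auxiliary head**: the exact architecture is open in the source
  material; a minimal conv → classifier → upsample head is used.
- **Profiles**: "tiny" (default in all tests) — 32-channel backbone, one
  residual block per stage, output stride 4; "resnet50-like" /
  "resnet101-like" — deeper stacks at output stride 8. Inputs not
  divisible by the stride are padded internally and cropped back.
- **Engine**: all layers run on a small NumPy reverse-mode autodiff module
  (`nnops`) with hand-derived gradients (im2col convolution, group
  normalization, adaptive average pooling, separable bilinear resampling,
  masked softmax cross-entropy), each checked against central finite
  differences in the test suite. Group normalization was chosen over batch
  statistics so that eval-mode forward passes are pure functions of
  (weights, input) and runs are bit-reproducible at any batch size.
- A noted inconsistency in the source description of the pooling grids
  ("three grids… 12 blocks" vs four scales summing to 50 bins): four
  scales (1, 2, 3, 6) are implemented, as stated everywhere else in the
  architecture description.

## Training

- Optimizer: SGD, momentum 0.9, weight decay 1e-4 (the published schedule
  names only the learning-rate law; these are its standard companions).
- Poly decay η(n) = η0·(1−n/N)^β with published constants η0 = 0.002,
  N = 200 rounds, β = 0.9. "Rounds" are interpreted as epochs; N is
  configurable.
- Published geometry: short side scaled to 1024, random 800×800 crops;
  augmentation is a random horizontal mirror (p = 0.5) and random resize
  in [0.75, 1.25] (range not published; a modest range documented here),
  applied identically to image and mask (image bilinear, mask
  nearest-neighbour). Images smaller than the crop after scaling are
  padded with the ignore label and a warning.
- 5-fold cross-validation with folds differing in size by at most one;
  the repeated-CV variant re-partitions with a re-derived seed.
- **Desk profile** (all tests, acceptance script): 96-px cores, 64-px
  crops, tiny backbone, batch 2. The overfit experiment trains on the
  full 96-px images, batch 4, η0 = 0.05 over 300 steps — full-view
  batches make 300-step memorization reliable where random 64-px crops
  leave it marginal. These sizes are the package's CPU-scale study
  conditions; the paper-scale profile is preserved in the config as the
  published setting.
- NaN/inf loss aborts with the epoch, step and learning rate.

## Evaluation

- Dice 2|A∩B|/(|A|+|B|); empty-vs-empty defined as 1.0 (perfect agreement
  on absence) with a warning.
- Hausdorff distance between 8-connectivity boundary pixel sets of the
  class regions (boundary, not filled region, is the standard reading of
  a "point set" of a label); undefined (NaN) when a class is absent from
  either mask, and such values are excluded from aggregate means.
- Cohen's kappa (p0−pe)/(1−pe), unweighted by default at the pixel level;
  the quadratic-weighted variant (squared ordinal distance on the sorted
  category union) is exposed for core-level comparisons. A single shared
  category used identically yields 1.0; differing sequences with pe = 1
  raise.
- Precision/recall/Jaccard/F1 per class from one-vs-rest counts;
  zero-denominator cases are 0 (conservative). Macro-F1 averages classes
  present in either mask; micro-F1 pools counts (and equals pixel accuracy
  when every pixel has exactly one predicted and one true class —
  asserted). Mean Dice averages classes present in the truth.
- Combined score: the challenge combination of κ and F1 is not public;
  the default is their arithmetic mean, and the combiner is pluggable.

## Core-level grading

Fractions are computed over non-ignore tissue pixels only. Majority class
= largest fraction; area ties break toward the higher pattern (clinically
conservative). Benign competes as a pattern, matching 4-class core-level
confusion matrices. Primary/secondary: largest and second-largest
patterns, minorities under 5% of tissue suppressed (secondary then equals
primary); with the threshold at 0 the rule reduces to area sorting.
Dichotomies: benign vs malignant from the majority class; Gleason 3 vs
4&5 only for malignant cores. Confusion matrices are row-normalized to
percentages; rows for classes absent from the truth are NaN rather than
silently zero.

## Reproducibility

Every stochastic component takes an explicit seed or Generator;
sub-streams are spawned with SeedSequence so per-rater and per-core
streams are independent but derived. Pure-NumPy compute on CPU makes
repeat runs bit-identical, which the pipeline test asserts on the full
simulate→fuse→train→predict→evaluate→grade chain.

A surfaced discrepancy, not resolved here: the source figure caption
equates STAPLE with pixel-wise majority voting, while its algorithm text
describes the EM estimator. Both are implemented and compared; they
coincide only in the limit of identically reliable raters.
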