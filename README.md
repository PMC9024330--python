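# pspgleason

Automatic prostate **Gleason grading** of tissue-microarray (TMA) core
images: multi-expert annotation fusion, pyramid-pooling semantic
segmentation, and core-level grade derivation, with the field's standard
evaluation metrics. The package is aimed at computational-pathology
researchers who need a fully testable, CPU-reproducible implementation of
this pipeline; every stage can be exercised on synthetic TMA-like images
with known ground truth, so no clinical data is required to run or verify
it.

## What it implements

**Label fusion (STAPLE).** Pathologists disagree, and some annotate only a
subset of images. STAPLE treats the true segmentation T and each rater j's
sensitivity p_j and specificity q_j as latent quantities and estimates both
by EM. For binary masks D_j the E-step gives the per-pixel posterior

    W_i = a_i / (a_i + b_i),
    a_i = g_i · Π_j p_j^{D_ij} (1−p_j)^{1−D_ij},
    b_i = (1−g_i) · Π_j (1−q_j)^{D_ij} q_j^{1−D_ij},

and the M-step re-estimates p_j = Σ W_i D_ij / Σ W_i and
q_j = Σ (1−W_i)(1−D_ij) / Σ (1−W_i). Multi-class masks (benign, Gleason
patterns 3, 4, 5) are fused one-vs-rest, normalized per pixel, and
argmax'd; ties go to the most experienced pathologist who annotated the
image. A pixel-wise majority-vote baseline is included.

**Segmentation network.** A residual backbone followed by a pyramid
pooling module — average pooling on 1×1, 2×2, 3×3 and 6×6 grids, a 1×1
convolution per branch, bilinear upsampling and concatenation with the
input features — and a per-pixel 4-class head. An auxiliary classifier on
the penultimate backbone stage adds a second cross-entropy term:

    L = L1 + α·L2,  α = 0.5.

Training uses poly learning-rate decay η = η0·(1 − n/N)^β with η0 = 0.002,
N = 200, β = 0.9, random resize + mirror augmentation, random crops
(800×800 from short-side-1024 images in the published profile) and 5-fold
cross-validation. The network and its training loop are implemented on a
small NumPy reverse-mode autodiff engine (`pspgleason.nnops`), so the whole
pipeline runs deterministically on one CPU.

**Evaluation and grading.** Dice, boundary Hausdorff distance, Cohen's
kappa (plain and quadratic-weighted), precision/recall/Jaccard/F1
(macro and micro), and a pluggable combined score (default: mean of κ and
macro-F1). Core-level grades take the class with the largest tissue area;
the clinical primary/secondary report ignores patterns under 5% of the
tissue; cores are also dichotomized benign vs malignant and Gleason 3 vs
4&5, with row-normalized confusion matrices.

## Worked example

```python
import numpy as np
from pspgleason import (SyntheticCoreSpec, generate_core, simulate_raters,
                        default_rater_profiles, staple_multiclass,
                        majority_vote, core_grade)

# a 128-px synthetic core: half pattern 3, half pattern 4
spec = SyntheticCoreSpec(image_size=128, region_layout=[(3, 0.5), (4, 0.5)], seed=5)
rgb, truth = generate_core(spec)

# six simulated pathologists (seniors more accurate, two partial-coverage)
ann = simulate_raters(truth, default_rater_profiles(), seed=9)
fused = staple_multiclass(ann)

tissue = truth != 255
print("raters present:", len(ann.rater_masks))
print("STAPLE accuracy:", round((fused.hard_mask[tissue] == truth[tissue]).mean(), 4))
print("majority-vote accuracy:", round((majority_vote(ann)[tissue] == truth[tissue]).mean(), 4))

grade = core_grade(fused.hard_mask)
print("core grade:", grade.majority_class, "primary/secondary:",
      (grade.primary, grade.secondary))
```

Output:

```
raters present: 5
STAPLE accuracy: 0.9916
majority-vote accuracy: 0.9921
core grade: 3 primary/secondary: (3, 4)
```

Five of the six raters covered this image (one partial-coverage rater
skipped it). Both fusers recover over 99% of the true pixel labels; with
raters this consistent the two are nearly indistinguishable — STAPLE's
advantage grows as rater quality becomes more heterogeneous, which the
parameter-recovery checks in the test suite measure directly. The fused
core is graded primary pattern 3 / secondary pattern 4, matching the
50/50 layout (the realized areas put pattern 3 marginally ahead).

The command-line interface mirrors the library:

```bash
pspgleason simulate --n-cores 12 --out data/ --seed 0
pspgleason fuse --manifest data/manifest.csv --out fused/
pspgleason pipeline --profile desk --out runs/demo --seed 0
```

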