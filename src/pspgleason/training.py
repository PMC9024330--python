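"""Data pipeline and optimization loop.

Published profile: short image side scaled to 1024 px, random 800x800
crops, random resize + horizontal mirror augmentation, poly learning-rate
decay eta = eta0 * (1 - n/N)^beta with eta0 = 0.002, N = 200 rounds,
beta = 0.9, and 5-fold cross-validation. The desk profile used throughout
the tests keeps the identical pipeline at CPU scale (96 px cores, 64 px
crops, tiny backbone).

Optimizer is SGD with momentum 0.9 and weight decay 1e-4 (the schedule's
standard companions). Everything is driven by explicit RNGs, so two runs
with the same seed produce identical logs on CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import nnops as N
from .metrics import evaluate_masks
from .model import CLASSES, IGNORE_LABEL, LossConfig, PSPSegmenter, total_loss

__all__ = [
    "TrainingSchedule",
    "FoldPlan",
    "poly_lr",
    "preprocess",
    "augment",
    "make_folds",
    "train",
    "labels_to_indices",
    "indices_to_labels",
]

_LABEL_TO_INDEX = np.full(256, IGNORE_LABEL, dtype=np.int64)
for _i, _c in enumerate(CLASSES):
    _LABEL_TO_INDEX[_c] = _i


def labels_to_indices(mask: np.ndarray) -> np.ndarray:
    """Map class labels {0,3,4,5} to indices 0..3; 255 stays 255."""
    return _LABEL_TO_INDEX[np.asarray(mask, dtype=np.int64)]


def indices_to_labels(idx: np.ndarray) -> np.ndarray:
    out = np.asarray(CLASSES, dtype=np.int64)[np.clip(idx, 0, len(CLASSES) - 1)]
    return np.where(np.asarray(idx) == IGNORE_LABEL, IGNORE_LABEL, out)


def poly_lr(n: int, eta0: float = 0.002, total: int = 200, beta: float = 0.9) -> float:
    """Poly decay eta0 * (1 - n/N)^beta for round n of N."""
    if n < 0 or n > total:
        raise ValueError(f"round {n} outside [0, {total}]")
    return eta0 * (1.0 - n / total) ** beta


@dataclass
class TrainingSchedule:
    """Learning-rate schedule parameters (published defaults)."""

    eta0: float = 0.002
    total_rounds: int = 200
    beta: float = 0.9

    def lr(self, n: int) -> float:
        return poly_lr(n, self.eta0, self.total_rounds, self.beta)


@dataclass
class FoldPlan:
    """k-fold assignment of image ids, folds differing in size by <= 1."""

    k: int
    assignments: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.assignments.items() if f == fold)


def make_folds(image_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    ids = list(image_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} images, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return FoldPlan(k, {img: i % k for i, img in enumerate(order)}, seed)


# ---------------------------------------------------------------------------
# geometry


def _resize_pair(image, mask, out_hw):
    img = _sk_resize(image, out_hw, order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    msk = _sk_resize(mask.astype(np.int64), out_hw, order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True).astype(np.int64)
    return img, msk


def preprocess(image: np.ndarray, mask: np.ndarray, short_side: int, crop: int, rng):
    """Scale the short image side to ``short_side`` (aspect preserved,
    image bilinear / mask nearest-neighbour), then take a random
    ``crop`` x ``crop`` patch. Images smaller than the crop after scaling
    are padded with the ignore label (mask) and zeros (image)."""
    image = np.asarray(image, dtype=np.float64)
    if image.max() > 1.5:
        image = image / 255.0
    mask = np.asarray(mask)
    h, w = mask.shape
    f = short_side / min(h, w)
    if h <= w:
        out_hw = (short_side, max(1, round(w * f)))
    else:
        out_hw = (max(1, round(h * f)), short_side)
    image, mask = _resize_pair(image, mask, out_hw)
    h, w = mask.shape
    if h < crop or w < crop:
        warnings.warn(f"image {h}x{w} smaller than crop {crop}; padding with ignore")
        ph, pw = max(0, crop - h), max(0, crop - w)
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)))
        mask = np.pad(mask, ((0, ph), (0, pw)), constant_values=IGNORE_LABEL)
        h, w = mask.shape
    oy = int(rng.integers(0, h - crop + 1))
    ox = int(rng.integers(0, w - crop + 1))
    return image[oy:oy + crop, ox:ox + crop], mask[oy:oy + crop, ox:ox + crop]


def augment(image: np.ndarray, mask: np.ndarray, rng, scale_range=(0.75, 1.25),
            flip=None, scale=None):
    """Random horizontal mirror (p = 0.5) and random resize, applied
    identically to image and mask; ``flip``/``scale`` override the draws
    (used to test the involution and identity properties). The patch size
    is preserved: upscales are centre-cropped, downscales padded with the
    ignore label."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if flip is None:
        flip = bool(rng.random() < 0.5)
    if scale is None:
        scale = float(rng.uniform(*scale_range))
    if flip:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if scale != 1.0:
        h, w = mask.shape
        nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
        img2, msk2 = _resize_pair(image, mask, (nh, nw))
        if nh >= h and nw >= w:
            oy, ox = (nh - h) // 2, (nw - w) // 2
            image = img2[oy:oy + h, ox:ox + w]
            mask = msk2[oy:oy + h, ox:ox + w]
        else:
            image = np.zeros((h, w, 3))
            mask = np.full((h, w), IGNORE_LABEL, dtype=np.int64)
            oy, ox = (h - nh) // 2, (w - nw) // 2
            image[oy:oy + nh, ox:ox + nw] = img2[:min(nh, h), :min(nw, w)]
            mask[oy:oy + nh, ox:ox + nw] = msk2[:min(nh, h), :min(nw, w)]
    return image, mask


# ---------------------------------------------------------------------------
# the loop


def _validate(model: PSPSegmenter, dataset) -> float:
    scores = []
    for image, mask in dataset:
        img = np.asarray(image, dtype=np.float64)
        if img.max() > 1.5:
            img = img / 255.0
        pred = model.predict(img)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores.append(evaluate_masks(pred, mask).mean_dsc)
    return float(np.mean(scores))


def train(model: PSPSegmenter, dataset, schedule: TrainingSchedule | None = None,
          loss_cfg: LossConfig | None = None, epochs: int = 50, batch_size: int = 2,
          seed: int = 0, val_dataset=None, short_side: int | None = None,
          crop: int | None = None, augment_data: bool = True, momentum: float = 0.9,
          weight_decay: float = 1e-4, eval_every: int = 1, max_steps: int | None = None):
    """Optimize ``model`` on ``dataset`` (a sequence of (image, mask) pairs,
    masks holding labels {0,3,4,5,255}).

    Returns ``(log, best_state)``: a per-epoch DataFrame with columns
    epoch, L, L1, L2, lr, val_dsc, and the weight state with the best
    validation DSC (validation defaults to the training set itself).
    Raises RuntimeError on a NaN loss.
    """
    if not len(dataset):
        raise ValueError("dataset is empty")
    schedule = schedule or TrainingSchedule(total_rounds=epochs)
    loss_cfg = loss_cfg or LossConfig()
    alpha = loss_cfg.alpha
    rng = np.random.default_rng(seed)
    opt = N.SGD(model.params(), lr=schedule.eta0, momentum=momentum,
                weight_decay=weight_decay)
    val_set = val_dataset if val_dataset is not None else dataset

    rows = []
    best = (-1.0, None)
    steps_done = 0
    n_items = len(dataset)
    for epoch in range(epochs):
        lr = schedule.lr(min(epoch, schedule.total_rounds))
        opt.lr = lr
        order = rng.permutation(n_items)
        l_sum = l1_sum = l2_sum = 0.0
        n_steps = 0
        for start in range(0, n_items, batch_size):
            if max_steps is not None and steps_done >= max_steps:
                break
            batch = order[start:start + batch_size]
            imgs, msks = [], []
            for bi in batch:
                image, mask = dataset[bi]
                if short_side is not None and crop is not None:
                    image, mask = preprocess(image, mask, short_side, crop, rng)
                else:
                    image = np.asarray(image, dtype=np.float64)
                    if image.max() > 1.5:
                        image = image / 255.0
                if augment_data:
                    image, mask = augment(image, mask, rng)
                imgs.append(image)
                msks.append(labels_to_indices(mask))
            x = np.stack(imgs)
            y = np.stack(msks)
            logits, aux, (h, w) = model.forward_batch(x, mode="train")
            ypad = np.full(logits.shape[0:1] + logits.shape[2:], IGNORE_LABEL, dtype=np.int64)
            ypad[:, :h, :w] = y
            l1 = N.softmax_cross_entropy(logits, ypad, ignore_label=IGNORE_LABEL)
            if aux is not None:
                l2 = N.softmax_cross_entropy(aux, ypad, ignore_label=IGNORE_LABEL)
                loss = N.add(l1, N.scale(l2, alpha))
            else:
                l2 = None
                loss = l1
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch} step {n_steps} (lr={lr:.2e})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            l_sum += loss.item()
            l1_sum += l1.item()
            l2_sum += l2.item() if l2 is not None else 0.0
            n_steps += 1
            steps_done += 1
        if n_steps == 0:
            break
        val_dsc = np.nan
        if (epoch + 1) % eval_every == 0 or epoch == epochs - 1:
            val_dsc = _validate(model, val_set)
            if val_dsc > best[0]:
                best = (val_dsc, {k: v.copy() for k, v in model.state_dict().items()})
        rows.append({"epoch": epoch, "L": l_sum / n_steps, "L1": l1_sum / n_steps,
                     "L2": l2_sum / n_steps, "lr": lr, "val_dsc": val_dsc})
        assert abs((l1_sum + alpha * l2_sum) / n_steps -
                   total_loss(l1_sum / n_steps, l2_sum / n_steps, alpha)) < 1e-9
        if max_steps is not None and steps_done >= max_steps:
            break
    log = pd.DataFrame(rows)
    if best[1] is None:
        best = (np.nan, model.state_dict())
    return log, best[1]
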