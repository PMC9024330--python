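"""Segmentation evaluation: Dice, Hausdorff, Cohen's kappa, P/R/JA/F1.

Conventions (documented, since the formulas leave corner cases open):
empty-vs-empty Dice is 1.0 (perfect agreement on absence, with a warning);
zero-denominator precision/recall/F1/JA are 0; Hausdorff distances are
computed between 8-connectivity boundary pixel sets of the class regions
and are undefined (NaN) when a class is absent from either mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

DEFAULT_CLASSES = (0, 3, 4, 5)
IGNORE_LABEL = 255

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "dice",
    "hausdorff",
    "boundary_points",
    "cohen_kappa",
    "prf_ja",
    "combined_score",
    "evaluate_masks",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest pixel counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Everything the evaluation computes for one (pred, truth) pair."""

    dsc: dict[int, float]
    mean_dsc: float
    hd: dict[int, float]
    kappa: float
    p0: float
    pe: float
    precision: dict[int, float]
    recall: dict[int, float]
    ja: dict[int, float]
    f1: dict[int, float]
    f1_macro: float
    f1_micro: float
    combined: float
    counts: dict[int, ConfusionCounts] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = {str(k): asdict(v) if isinstance(v, ConfusionCounts) else v
                       for k, v in d["counts"].items()}
        for key in ("dsc", "hd", "precision", "recall", "ja", "f1"):
            d[key] = {str(k): v for k, v in d[key].items()}
        return d


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|) of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(n, 2) coordinates of the 8-connectivity boundary of a binary region."""
    mask = np.asarray(mask, dtype=bool)
    interior = binary_erosion(mask, structure=np.ones((3, 3)))
    return np.argwhere(mask & ~interior)


def hausdorff(xs: np.ndarray, ys: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two Euclidean point sets."""
    xs = np.atleast_2d(np.asarray(xs, dtype=np.float64))
    ys = np.atleast_2d(np.asarray(ys, dtype=np.float64))
    if xs.size == 0 or ys.size == 0:
        raise ValueError("Hausdorff distance is undefined for an empty point set")
    d_xy = cKDTree(ys).query(xs)[0].max()      # max over x of min over y
    d_yx = cKDTree(xs).query(ys)[0].max()
    return float(max(d_xy, d_yx))


def cohen_kappa(a, b, weighting: str = "none"):
    """Cohen's kappa (p0 - pe) / (1 - pe); optionally quadratic-weighted.

    Returns ``(kappa, p0, pe)`` where for the weighted variant p0 and pe are
    the weighted observed/chance agreements. Categories are the sorted
    union of labels in both sequences (the usual ordinal convention for the
    quadratic weights).
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size or a.size == 0:
        raise ValueError("sequences must be non-empty and of equal length")
    cats = np.union1d(a, b)
    k = len(cats)
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    cm = np.zeros((k, k))
    np.add.at(cm, (ai, bi), 1)
    n = cm.sum()
    if k == 1:
        return 1.0, 1.0, 1.0        # a single shared category used identically
    if weighting == "none":
        w = 1.0 - np.eye(k)
    elif weighting == "quadratic":
        idx = np.arange(k)
        w = ((idx[:, None] - idx[None, :]) ** 2) / (k - 1) ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    expected = np.outer(cm.sum(axis=1), cm.sum(axis=0)) / n
    p0 = 1.0 - (w * cm).sum() / n
    pe = 1.0 - (w * expected).sum() / n
    if pe >= 1.0:
        if np.array_equal(a, b):
            return 1.0, p0, pe
        raise ValueError("kappa undefined: chance agreement is 1 but sequences differ")
    return float((p0 - pe) / (1.0 - pe)), float(p0), float(pe)


def prf_ja(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(precision, recall, Jaccard, F1) from one-vs-rest counts; any
    zero-denominator case yields 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    ja = tp / (tp + fn + fp) if tp + fn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, ja, f1


def combined_score(kappa: float, f1: float, combiner=None) -> float:
    """Challenge-style combination of kappa and F1; the default is their
    arithmetic mean (the combination is pluggable)."""
    if combiner is None:
        return 0.5 * (kappa + f1)
    return combiner(kappa, f1)


def evaluate_masks(pred: np.ndarray, truth: np.ndarray, classes=DEFAULT_CLASSES,
                   ignore_label: int = IGNORE_LABEL) -> MetricsReport:
    """Full per-class and aggregate report for one predicted mask.

    Pixels where either mask carries the ignore label are excluded. Mean
    DSC averages over classes present in the truth; macro-F1 averages over
    classes present in either mask; micro-F1 pools counts over all classes.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a shape")
    valid = (truth != ignore_label) & (pred != ignore_label)
    if not valid.any():
        raise ValueError("no evaluable pixels (everything is ignore)")
    p = pred[valid]
    t = truth[valid]
    n = p.size

    counts: dict[int, ConfusionCounts] = {}
    dscs, hds, precs, recs, jas, f1s = {}, {}, {}, {}, {}, {}
    for c in classes:
        pc = p == c
        tc = t == c
        tp = int((pc & tc).sum())
        fp = int((pc & ~tc).sum())
        fn = int((~pc & tc).sum())
        counts[c] = ConfusionCounts(tp, fp, fn, n - tp - fp - fn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dscs[c] = dice(pc, tc)
        precs[c], recs[c], jas[c], f1s[c] = prf_ja(counts[c])
        pb = boundary_points((pred == c) & valid)
        tb = boundary_points((truth == c) & valid)
        hds[c] = hausdorff(pb, tb) if len(pb) and len(tb) else float("nan")

    present_truth = [c for c in classes if (t == c).any()]
    present_any = [c for c in classes if (t == c).any() or (p == c).any()]
    mean_dsc = float(np.mean([dscs[c] for c in present_truth]))
    f1_macro = float(np.mean([f1s[c] for c in present_any]))
    tp_all = sum(counts[c].tp for c in classes)
    fp_all = sum(counts[c].fp for c in classes)
    fn_all = sum(counts[c].fn for c in classes)
    pr_mi = tp_all / (tp_all + fp_all) if tp_all + fp_all else 0.0
    rc_mi = tp_all / (tp_all + fn_all) if tp_all + fn_all else 0.0
    f1_micro = 2 * pr_mi * rc_mi / (pr_mi + rc_mi) if pr_mi + rc_mi else 0.0
    kappa, p0, pe = cohen_kappa(t, p)
    return MetricsReport(
        dsc=dscs, mean_dsc=mean_dsc, hd=hds, kappa=kappa, p0=p0, pe=pe,
        precision=precs, recall=recs, ja=jas, f1=f1s,
        f1_macro=f1_macro, f1_micro=float(f1_micro),
        combined=combined_score(kappa, f1_macro), counts=counts)
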