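"""Core-level Gleason grading from pixel-level masks.

A whole-core grade is derived from a segmentation mask by ignoring the
non-tissue background and taking the class with the largest area. The
clinical primary/secondary report takes the largest-area pattern as
primary and the second-largest as secondary, except that patterns covering
less than 5% of the tissue are ignored (secondary then defaults to the
primary). Cores also get two dichotomies: benign vs malignant, and — for
malignant cores — low-risk (pattern 3) vs high-risk (patterns 4 and 5).

Area ties are broken toward the higher Gleason pattern (the clinically
conservative choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CLASSES = (0, 3, 4, 5)
IGNORE_LABEL = 255

__all__ = [
    "CoreGrade",
    "core_grade",
    "primary_secondary",
    "dichotomize",
    "core_confusion",
]


@dataclass
class CoreGrade:
    """Core-level result: majority class, primary/secondary, dichotomies."""

    majority_class: int
    primary: int
    secondary: int
    class_fractions: dict[int, float] = field(default_factory=dict)
    malignant: bool = False
    high_risk: bool = False


def _fractions(mask: np.ndarray, classes, ignore_label) -> dict[int, float]:
    mask = np.asarray(mask)
    tissue = mask != ignore_label
    n = int(tissue.sum())
    if n == 0:
        raise ValueError("mask has no tissue pixels (all ignore)")
    labels = mask[tissue]
    bad = set(np.unique(labels).tolist()) - set(classes)
    if bad:
        raise ValueError(f"mask contains labels {sorted(bad)} outside {sorted(classes)}")
    return {c: int((labels == c).sum()) / n for c in classes}


def _ranked(fracs: dict[int, float]) -> list[tuple[int, float]]:
    """Classes by descending area; ties go to the higher pattern."""
    return sorted(fracs.items(), key=lambda kv: (-kv[1], -kv[0]))


def core_grade(mask: np.ndarray, classes=DEFAULT_CLASSES,
               ignore_label: int = IGNORE_LABEL, min_frac: float = 0.05) -> CoreGrade:
    """Grade one core from its label mask (largest-proportion rule)."""
    fracs = _fractions(mask, classes, ignore_label)
    majority = _ranked(fracs)[0][0]
    primary, secondary = primary_secondary(mask, min_frac=min_frac, classes=classes,
                                           ignore_label=ignore_label)
    malignant = majority != 0
    return CoreGrade(
        majority_class=majority, primary=primary, secondary=secondary,
        class_fractions=fracs, malignant=malignant,
        high_risk=malignant and majority in (4, 5))


def primary_secondary(mask: np.ndarray, min_frac: float = 0.05, classes=DEFAULT_CLASSES,
                      ignore_label: int = IGNORE_LABEL) -> tuple[int, int]:
    """Primary = largest-area pattern; secondary = second largest with at
    least ``min_frac`` of the tissue, else the primary again. Minorities
    under the threshold are never reported."""
    fracs = _fractions(mask, classes, ignore_label)
    ranked = [(c, f) for c, f in _ranked(fracs) if f > 0]
    primary = ranked[0][0]
    secondary = primary
    if len(ranked) > 1 and ranked[1][1] >= min_frac:
        secondary = ranked[1][0]
    return primary, secondary


def dichotomize(grade: CoreGrade) -> tuple[str, str | None]:
    """(benign|malignant, low_risk|high_risk|None).

    The Gleason-3 vs 4&5 split applies only to malignant cores; for benign
    cores the second element is None (not applicable).
    """
    if not grade.malignant:
        return "benign", None
    return "malignant", "high_risk" if grade.high_risk else "low_risk"


def core_confusion(pred_grades, true_grades, classes=DEFAULT_CLASSES) -> pd.DataFrame:
    """Row-normalized percentage confusion matrix over core-level grades.

    Rows are true classes, columns predicted; each row with any cores sums
    to 100. Rows for classes absent from the truth are NaN. Accepts lists
    of class labels or of CoreGrade objects (their majority class is used).
    """
    def as_label(g):
        return g.majority_class if isinstance(g, CoreGrade) else int(g)

    p = [as_label(g) for g in pred_grades]
    t = [as_label(g) for g in true_grades]
    if len(p) != len(t) or not p:
        raise ValueError("need equal-length, non-empty grade lists")
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)))
    for ti, pi in zip(t, p):
        cm[idx[ti], idx[pi]] += 1
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * cm / row_sums, np.nan)
    return pd.DataFrame(pct, index=list(classes), columns=list(classes))
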