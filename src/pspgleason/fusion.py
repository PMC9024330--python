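"""Multi-expert annotation fusion via STAPLE.

Pathologist annotations of the same TMA core disagree; network training
needs a single ground-truth mask. STAPLE (Simultaneous Truth and
Performance Level Estimation) treats the unknown true segmentation and each
rater's sensitivity/specificity as latent quantities and estimates both by
EM. The binary E-step computes the per-pixel posterior that the true label
is foreground,

    W_i = a_i / (a_i + b_i),
    a_i = g_i * prod_j p_j^{D_ij} (1-p_j)^{1-D_ij},
    b_i = (1-g_i) * prod_j (1-q_j)^{D_ij} q_j^{1-D_ij},

where D_ij is rater j's decision at pixel i, g_i the foreground prior,
p_j the sensitivity and q_j the specificity; the M-step re-estimates

    p_j = sum_i W_i D_ij / sum_i W_i,
    q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i).

The multi-class extension runs one-vs-rest binary STAPLE per Gleason class,
normalizes the stacked posteriors per pixel and takes the argmax; pixels
where the maximum is attained by more than one class are resolved by
seniority — the most experienced pathologist who annotated the image wins.
A pixel-wise majority-vote baseline with the same tie rule is provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IGNORE_LABEL = 255
DEFAULT_CLASSES = (0, 3, 4, 5)
_EPS = 1e-12
_TIE_TOL = 1e-9

__all__ = [
    "AnnotationSet",
    "RaterPerformance",
    "FusedLabel",
    "staple_binary",
    "staple_multiclass",
    "resolve_ties",
    "majority_vote",
]


@dataclass
class RaterPerformance:
    """One rater's estimated quality on one one-vs-rest sub-problem."""

    rater_id: str
    sensitivity: float
    specificity: float
    class_label: int


@dataclass
class AnnotationSet:
    """One image's per-rater label masks plus rater seniority.

    ``seniority`` maps rater_id -> rank, rank 1 being the most experienced.
    The map may contain raters who did not annotate this image (per-image
    missingness); every annotating rater must have a rank, and ranks must be
    unique.
    """

    image_id: str
    rater_masks: dict[str, np.ndarray]
    seniority: dict[str, int]

    def __post_init__(self):
        if not self.rater_masks:
            raise ValueError("AnnotationSet needs at least one rater mask")
        shapes = {m.shape for m in self.rater_masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"rater masks have mixed shapes: {sorted(shapes)}")
        missing = set(self.rater_masks) - set(self.seniority)
        if missing:
            raise ValueError(f"raters without seniority rank: {sorted(missing)}")
        ranks = list(self.seniority.values())
        if len(set(ranks)) != len(ranks):
            raise ValueError("seniority ranks must be unique")

    @property
    def shape(self):
        return next(iter(self.rater_masks.values())).shape

    def raters_by_seniority(self) -> list[str]:
        """Annotating raters, most experienced first."""
        return sorted(self.rater_masks, key=lambda r: self.seniority[r])


@dataclass
class FusedLabel:
    """STAPLE consensus: per-class probability fields, hard mask, ties."""

    image_id: str
    prob_fields: dict[int, np.ndarray]
    hard_mask: np.ndarray
    tie_pixels: set[tuple[int, int]]
    performances: list[RaterPerformance] = field(default_factory=list)
    converged: bool = True


# ---------------------------------------------------------------------------
# binary STAPLE


def staple_binary(binary_masks, prior=None, init_p: float = 0.99999, init_q: float = 0.99999,
                  tol: float = 1e-6, max_iter: int = 100, estimate_performance: bool = True):
    """Binary STAPLE EM on a list of {0,1} masks of one shape.

    Returns ``(W, performances, info)`` where ``W`` is the posterior
    foreground-probability field, ``performances`` the estimated (p, q) per
    rater (in input order) and ``info`` carries the log-likelihood
    trajectory, iteration count and flags.

    ``prior`` is the per-pixel foreground prior: a scalar, a field of the
    mask shape, or None for the data-driven default (mean foreground
    fraction across raters). ``estimate_performance=False`` skips the
    M-step — a single E-step at the supplied (p, q), which is the
    closed-form Bayes posterior.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not binary_masks:
        raise ValueError("need at least one mask")
    shapes = {np.asarray(m).shape for m in binary_masks}
    if len(shapes) != 1:
        raise ValueError(f"masks have mixed shapes: {sorted(shapes)}")
    shape = shapes.pop()
    d = np.stack([np.asarray(m, dtype=np.float64).ravel() for m in binary_masks])  # (J, M)
    j, m = d.shape

    if prior is None:
        g = np.full(m, d.mean())
    elif np.isscalar(prior):
        g = np.full(m, float(prior))
    else:
        g = np.asarray(prior, dtype=np.float64).ravel()
        if g.size != m:
            raise ValueError("prior field shape does not match masks")

    info = {"n_iter": 0, "converged": True, "degenerate": False, "log_likelihood": []}
    if np.all(g <= 0):
        # nothing supports foreground (e.g. all-empty masks with zero prior)
        info["degenerate"] = True
        w = np.zeros(shape)
        perfs = [(init_p, init_q)] * j
        return w, perfs, info

    g = np.clip(g, _EPS, 1 - _EPS)
    p = np.broadcast_to(np.asarray(init_p, dtype=np.float64), (j,)).copy()
    q = np.broadcast_to(np.asarray(init_q, dtype=np.float64), (j,)).copy()
    w = None

    for it in range(max_iter):
        log_a = np.log(g) + d.T @ np.log(p) + (1 - d).T @ np.log(1 - p)
        log_b = np.log1p(-g) + d.T @ np.log(1 - q) + (1 - d).T @ np.log(q)
        info["log_likelihood"].append(float(np.logaddexp(log_a, log_b).sum()))
        w_new = 1.0 / (1.0 + np.exp(log_b - log_a))
        info["n_iter"] = it + 1
        delta = np.inf if w is None else float(np.abs(w_new - w).max())
        w = w_new
        if not estimate_performance:
            break
        if delta < tol:
            break
        sw = w.sum()
        sc = (1 - w).sum()
        p = np.clip((d * w).sum(axis=1) / max(sw, _EPS), _EPS, 1 - _EPS)
        q = np.clip(((1 - d) * (1 - w)).sum(axis=1) / max(sc, _EPS), _EPS, 1 - _EPS)
    else:
        info["converged"] = False

    perfs = list(zip(p.tolist(), q.tolist()))
    return w.reshape(shape), perfs, info


# ---------------------------------------------------------------------------
# multi-class extension


def _check_labels(ann: AnnotationSet, classes, ignore_label):
    allowed = set(classes) | {ignore_label}
    for rid, mask in ann.rater_masks.items():
        found = set(np.unique(mask).tolist())
        bad = found - allowed
        if bad:
            raise ValueError(f"rater {rid!r} uses labels {sorted(bad)} outside classes {sorted(classes)}")


def staple_multiclass(ann: AnnotationSet, classes=DEFAULT_CLASSES, prior_mode: str = "data",
                      tol: float = 1e-6, max_iter: int = 100,
                      ignore_label: int = IGNORE_LABEL) -> FusedLabel:
    """One-vs-rest STAPLE per class, normalized, argmax with seniority ties.

    Pixels that every rater marks as ``ignore_label`` (non-tissue) are
    excluded from the EM and copied through as ignore. A rater's ignore
    pixel counts as a background vote in every one-vs-rest problem.
    """
    classes = tuple(classes)
    _check_labels(ann, classes, ignore_label)
    rater_order = ann.raters_by_seniority()
    stack = np.stack([np.asarray(ann.rater_masks[r]) for r in rater_order])   # (J, H, W)
    h, w = ann.shape
    all_ignore = np.all(stack == ignore_label, axis=0)
    valid = ~all_ignore
    flat = stack[:, valid]                                                    # (J, M)

    probs = np.zeros((len(classes), int(valid.sum())))
    performances: list[RaterPerformance] = []
    converged = True
    for ci, c in enumerate(classes):
        d = [(flat[ji] == c).astype(np.float64) for ji in range(len(rater_order))]
        if prior_mode == "data":
            prior = None                      # mean foreground fraction (default)
        elif prior_mode == "uniform":
            prior = 1.0 / len(classes)
        else:
            raise ValueError(f"unknown prior_mode {prior_mode!r}")
        wfield, perfs, info = staple_binary(d, prior=prior, tol=tol, max_iter=max_iter)
        converged &= info["converged"]
        probs[ci] = wfield.ravel()
        if not info["degenerate"]:
            for rid, (p, q) in zip(rater_order, perfs):
                performances.append(RaterPerformance(rid, p, q, c))

    tot = probs.sum(axis=0)
    empty = tot <= 0
    probs[:, empty] = 1.0 / len(classes)
    tot[empty] = 1.0
    probs /= tot

    top = probs.max(axis=0)
    is_tie = (probs >= top - _TIE_TOL).sum(axis=0) > 1
    argmax = probs.argmax(axis=0)

    hard = np.full((h, w), ignore_label, dtype=np.int64)
    hard[valid] = np.asarray(classes)[argmax]
    ys, xs = np.nonzero(valid)
    tie_pixels = {(int(y), int(x)) for y, x in zip(ys[is_tie], xs[is_tie])}
    hard = resolve_ties(hard, tie_pixels, ann, ignore_label=ignore_label)

    prob_fields = {}
    for ci, c in enumerate(classes):
        f = np.zeros((h, w))
        f[valid] = probs[ci]
        prob_fields[c] = f
    return FusedLabel(ann.image_id, prob_fields, hard, tie_pixels, performances, converged)


def resolve_ties(hard_mask: np.ndarray, tie_pixels, ann: AnnotationSet,
                 ignore_label: int = IGNORE_LABEL) -> np.ndarray:
    """Give each tied pixel the label of the most experienced present rater.

    If the most experienced rater did not annotate the image (or marked the
    pixel ignore), the next rater in the seniority ranking is used.
    """
    out = np.array(hard_mask, copy=True)
    if not tie_pixels:
        return out
    order = ann.raters_by_seniority()
    for (y, x) in tie_pixels:
        for rid in order:
            lab = int(ann.rater_masks[rid][y, x])
            if lab != ignore_label:
                out[y, x] = lab
                break
    return out


def majority_vote(ann: AnnotationSet, classes=DEFAULT_CLASSES,
                  ignore_label: int = IGNORE_LABEL) -> np.ndarray:
    """Pixel-wise modal label; ties broken by seniority, like STAPLE."""
    classes = tuple(classes)
    _check_labels(ann, classes, ignore_label)
    rater_order = ann.raters_by_seniority()
    stack = np.stack([np.asarray(ann.rater_masks[r]) for r in rater_order])
    counts = np.stack([(stack == c).sum(axis=0) for c in classes])            # (K, H, W)
    total = counts.sum(axis=0)
    top = counts.max(axis=0)
    hard = np.asarray(classes)[counts.argmax(axis=0)]
    hard[total == 0] = ignore_label                                           # all raters ignore
    tied = ((counts == top).sum(axis=0) > 1) & (total > 0)
    ys, xs = np.nonzero(tied)
    tie_pixels = {(int(y), int(x)) for y, x in zip(ys, xs)}
    return resolve_ties(hard, tie_pixels, ann, ignore_label=ignore_label)
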