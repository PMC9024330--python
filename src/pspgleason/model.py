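"""Pyramid scene-parsing segmentation network for Gleason-pattern masks.

The network is the classic pyramid-parsing layout: a residual backbone,
a pyramid pooling module (PPM) that average-pools the final feature map on
1x1, 2x2, 3x3 and 6x6 grids, reduces each pooled map with a 1x1 convolution,
bilinearly upsamples it back and concatenates everything with the input
features, and a per-pixel classifier head. During training an auxiliary
classifier attached to the penultimate backbone stage adds a second
cross-entropy term, combined as ``L = L1 + alpha * L2`` with alpha = 0.5.
Only the main head is used at inference.

Classes are the four Gleason groups {benign, pattern 3, pattern 4,
pattern 5}; mask label 255 marks non-tissue and is excluded from every loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nnops as N
from .nnops import Tensor

CLASSES = (0, 3, 4, 5)
IGNORE_LABEL = 255

__all__ = [
    "SegModelConfig",
    "LossConfig",
    "PSPSegmenter",
    "build_model",
    "pyramid_pool",
    "total_loss",
    "save_checkpoint",
    "load_checkpoint",
    "CLASSES",
    "IGNORE_LABEL",
]


@dataclass
class SegModelConfig:
    """Architecture hyperparameters.

    ``backbone_depth`` selects the profile: "tiny" is a CPU-scale residual
    backbone with output stride 4 used throughout the tests; the
    "resnet50-like"/"resnet101-like" profiles use deeper stacks at output
    stride 8 (dilated final stages). ``ppm_branch_channels`` defaults to
    C / len(bins) so the PPM doubles the channel count, the standard choice.
    """

    n_classes: int = 4
    backbone_depth: str = "tiny"
    backbone_channels: int = 32
    ppm_bins: tuple[int, ...] = (1, 2, 3, 6)
    ppm_branch_channels: int | None = None
    output_stride: int = 4
    aux_enabled: bool = True
    align_corners: bool = True       # bilinear upsampling convention, pinned
    gn_groups: int = 8

    def __post_init__(self):
        self.ppm_bins = tuple(self.ppm_bins)
        if list(self.ppm_bins) != sorted(self.ppm_bins) or min(self.ppm_bins) < 1:
            raise ValueError("ppm_bins must be ascending and >= 1")
        if self.ppm_branch_channels is None:
            if self.backbone_channels % len(self.ppm_bins):
                raise ValueError(
                    f"backbone_channels {self.backbone_channels} not divisible by "
                    f"{len(self.ppm_bins)} bins; set ppm_branch_channels explicitly")
            self.ppm_branch_channels = self.backbone_channels // len(self.ppm_bins)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ppm_bins"] = list(self.ppm_bins)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SegModelConfig":
        return cls(**d)


@dataclass
class LossConfig:
    """Composite-loss bookkeeping: total = main + alpha * auxiliary."""

    alpha: float = 0.5
    main: float = 0.0       # L1, main-branch cross-entropy
    aux: float = 0.0        # L2, auxiliary-branch cross-entropy
    total: float = 0.0      # L = L1 + alpha * L2

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def total_loss(l1: float, l2: float, alpha: float = 0.5) -> float:
    """Composite training loss ``L = L1 + alpha * L2``.

    Both terms are cross-entropies and must be non-negative and finite.
    """
    if not (np.isfinite(l1) and np.isfinite(l2)):
        raise ValueError("loss terms must be finite")
    if l1 < 0 or l2 < 0:
        raise ValueError("cross-entropy terms cannot be negative")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return l1 + alpha * l2


# ---------------------------------------------------------------------------
# functional pyramid pooling


def pyramid_pool(feature: np.ndarray, bins=(1, 2, 3, 6), branch_channels: int | None = None,
                 conv_weights=None, conv_biases=None, align_corners: bool = True) -> np.ndarray:
    """Pyramid pooling of a single ``(C, h, w)`` feature map.

    For each grid size ``b``: adaptive average pooling to ``b x b``, a 1x1
    convolution to ``branch_channels``, bilinear upsampling back to
    ``(h, w)``; the input map and all branch outputs are concatenated along
    the channel axis, giving ``C + len(bins) * branch_channels`` channels.

    ``conv_weights`` is a list of ``(branch_channels, C)`` matrices (one per
    bin). When omitted, the 1x1 convolutions are identity maps, which
    requires ``branch_channels == C``; this is the form used to verify the
    pooling/upsampling arithmetic in isolation.
    """
    feature = np.asarray(feature, dtype=np.float64)
    c, h, w = feature.shape
    bins = tuple(bins)
    for b in bins:
        if b > min(h, w):
            raise ValueError(f"pyramid bin {b} larger than feature map {h}x{w}")
    if branch_channels is None:
        branch_channels = c
    if conv_weights is None:
        if branch_channels != c:
            raise ValueError("identity 1x1 convolution requires branch_channels == C")
        conv_weights = [np.eye(c)] * len(bins)
    if conv_biases is None:
        conv_biases = [np.zeros(branch_channels)] * len(bins)

    x = Tensor(feature[None])
    parts = [feature]
    for b, wmat, bias in zip(bins, conv_weights, conv_biases):
        pooled = N.adaptive_avg_pool2d(x, b)
        wt = Tensor(np.asarray(wmat, dtype=np.float64).reshape(branch_channels, c, 1, 1))
        bt = Tensor(np.asarray(bias, dtype=np.float64))
        conv = N.conv2d(pooled, wt, bt)
        up = N.upsample_bilinear(conv, (h, w), align_corners=align_corners)
        parts.append(up.data[0])
    return np.concatenate(parts, axis=0)


# ---------------------------------------------------------------------------
# the network


def _he_conv(rng, f, c, k):
    std = np.sqrt(2.0 / (c * k * k))
    return Tensor(rng.normal(0.0, std, size=(f, c, k, k)), requires_grad=True)


class _ConvGNReLU:
    """conv(k) -> group norm -> ReLU."""

    def __init__(self, rng, cin, cout, k, stride, groups):
        self.w = _he_conv(rng, cout, cin, k)
        self.gamma = Tensor(np.ones(cout), requires_grad=True)
        self.beta = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.pad, self.groups = stride, k // 2, groups

    def __call__(self, x):
        y = N.conv2d(x, self.w, None, stride=self.stride, pad=self.pad)
        y = N.group_norm(y, self.gamma, self.beta, self.groups)
        return N.relu(y)

    def params(self):
        return [self.w, self.gamma, self.beta]


class _ResidualBlock:
    """Two 3x3 conv+GN layers with an identity skip connection."""

    def __init__(self, rng, channels, groups):
        self.c1 = _ConvGNReLU(rng, channels, channels, 3, 1, groups)
        self.w2 = _he_conv(rng, channels, channels, 3)
        self.gamma2 = Tensor(np.ones(channels), requires_grad=True)
        self.beta2 = Tensor(np.zeros(channels), requires_grad=True)
        self.groups = groups

    def __call__(self, x):
        y = self.c1(x)
        y = N.conv2d(y, self.w2, None, stride=1, pad=1)
        y = N.group_norm(y, self.gamma2, self.beta2, self.groups)
        return N.relu(N.add(y, x))

    def params(self):
        return self.c1.params() + [self.w2, self.gamma2, self.beta2]


class _PPMBranch:
    def __init__(self, rng, bin_size, cin, cout, groups):
        self.bin = bin_size
        self.conv = _ConvGNReLU(rng, cin, cout, 1, 1, groups)

    def __call__(self, x, size, align_corners):
        pooled = N.adaptive_avg_pool2d(x, self.bin)
        return N.upsample_bilinear(self.conv(pooled), size, align_corners=align_corners)

    def params(self):
        return self.conv.params()


class PSPSegmenter:
    """Residual backbone + pyramid pooling + main and auxiliary heads.

    ``forward(image, mode)`` maps an (H, W, 3) float image in [0, 1] to
    per-pixel class scores (n_classes, H, W); in "train" mode it also
    returns auxiliary scores from the penultimate backbone stage. Sizes not
    divisible by the output stride are padded internally and cropped back.
    """

    _DEPTHS = {"tiny": 1, "resnet50-like": 3, "resnet101-like": 6}

    def __init__(self, cfg: SegModelConfig, seed: int = 0):
        if cfg.backbone_depth not in self._DEPTHS:
            raise ValueError(f"unknown backbone_depth {cfg.backbone_depth!r}")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.backbone_channels
        g = cfg.gn_groups
        n_blocks = self._DEPTHS[cfg.backbone_depth]
        # stem: two stride-2 convolutions -> output stride 4
        self.stem1 = _ConvGNReLU(rng, 3, c // 2, 3, 2, max(1, g // 2))
        self.stem2 = _ConvGNReLU(rng, c // 2, c, 3, 2, g)
        self.stage1 = [_ResidualBlock(rng, c, g) for _ in range(n_blocks)]
        self.stage2 = [_ResidualBlock(rng, c, g) for _ in range(n_blocks)]   # aux taps here
        self.stage3 = [_ResidualBlock(rng, c, g) for _ in range(n_blocks)]
        nb = len(cfg.ppm_bins)
        bc = cfg.ppm_branch_channels
        self.ppm = [_PPMBranch(rng, b, c, bc, min(g, bc)) for b in cfg.ppm_bins]
        head_in = c + nb * bc
        self.head = _ConvGNReLU(rng, head_in, c, 3, 1, g)
        self.cls_w = _he_conv(rng, cfg.n_classes, c, 1)
        self.cls_b = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
        # auxiliary head: minimal conv -> classifier -> upsample
        self.aux = _ConvGNReLU(rng, c, c // 2, 3, 1, max(1, g // 2))
        self.aux_w = _he_conv(rng, cfg.n_classes, c // 2, 1)
        self.aux_b = Tensor(np.zeros(cfg.n_classes), requires_grad=True)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Tensor]:
        ps = self.stem1.params() + self.stem2.params()
        for blk in self.stage1 + self.stage2 + self.stage3:
            ps += blk.params()
        for br in self.ppm:
            ps += br.params()
        ps += self.head.params() + [self.cls_w, self.cls_b]
        if self.cfg.aux_enabled:
            ps += self.aux.params() + [self.aux_w, self.aux_b]
        return ps

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- forward ------------------------------------------------------------

    def forward_batch(self, images: np.ndarray, mode: str = "eval"):
        """Forward a batch of (N, H, W, 3) images; returns score Tensors."""
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError("expected RGB input of shape (N, H, W, 3)")
        n, h, w, _ = images.shape
        s = self.cfg.output_stride
        # pad to a multiple of the output stride so every bin fits
        min_side = s * max(self.cfg.ppm_bins)
        hp = max(int(np.ceil(h / s)) * s, min_side)
        wp = max(int(np.ceil(w / s)) * s, min_side)
        x = np.zeros((n, 3, hp, wp))
        x[:, :, :h, :w] = images.transpose(0, 3, 1, 2)
        t = Tensor(x)

        y = self.stem2(self.stem1(t))
        for blk in self.stage1:
            y = blk(y)
        for blk in self.stage2:
            y = blk(y)
        penult = y
        for blk in self.stage3:
            y = blk(y)

        fh, fw = y.shape[2], y.shape[3]
        parts = [y] + [br(y, (fh, fw), self.cfg.align_corners) for br in self.ppm]
        feat = N.concat(parts, axis=1)
        logits = N.conv2d(self.head(feat), self.cls_w, self.cls_b)
        logits = N.upsample_bilinear(logits, (hp, wp), align_corners=self.cfg.align_corners)

        if mode == "train" and self.cfg.aux_enabled:
            aux = N.conv2d(self.aux(penult), self.aux_w, self.aux_b)
            aux = N.upsample_bilinear(aux, (hp, wp), align_corners=self.cfg.align_corners)
            return logits, aux, (h, w)
        return logits, None, (h, w)

    def forward(self, image: np.ndarray, mode: str = "eval"):
        """Single-image forward; returns (scores, aux_scores or None)."""
        logits, aux, (h, w) = self.forward_batch(np.asarray(image, dtype=np.float64)[None], mode)
        main = logits.data[0, :, :h, :w]
        return (main, aux.data[0, :, :h, :w] if aux is not None else None)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Hard class-label mask (values from CLASSES) for one RGB image."""
        scores, _ = self.forward(image, mode="eval")
        idx = scores.argmax(axis=0)
        return np.asarray(CLASSES, dtype=np.int64)[idx]

    def softmax(self, image: np.ndarray) -> np.ndarray:
        scores, _ = self.forward(image, mode="eval")
        z = scores - scores.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    # -- serialization ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, p in enumerate(self.params()):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float64)


def build_model(cfg: SegModelConfig, seed: int = 0) -> PSPSegmenter:
    """Instantiate the segmenter with seeded He-normal initialization."""
    return PSPSegmenter(cfg, seed=seed)


def save_checkpoint(model: PSPSegmenter, path: str | Path):
    """Weights as .npz with a JSON config sidecar."""
    path = Path(path)
    with open(path, "wb") as fh:     # keep the exact filename (np.savez appends .npz)
        np.savez(fh, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(model.cfg.to_dict(), indent=1))


def load_checkpoint(path: str | Path) -> PSPSegmenter:
    path = Path(path)
    cfg = SegModelConfig.from_dict(json.loads(path.with_suffix(path.suffix + ".json").read_text()))
    model = PSPSegmenter(cfg, seed=0)
    with np.load(path) as st:
        model.load_state_dict(dict(st))
    return model
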