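"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the pyramid scene-parsing segmenter needs:
2-D convolution (im2col), ReLU, residual addition, group normalization,
adaptive average pooling, bilinear upsampling, channel concatenation and
softmax cross-entropy with an ignore label, plus SGD with momentum.

All arrays are ``float64`` NCHW. Every gradient here is hand-derived and is
checked against central finite differences in the test suite. The engine is
deterministic: identical inputs and parameters give bit-identical outputs on
CPU, which the training loop relies on for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "relu",
    "add",
    "scale",
    "concat",
    "group_norm",
    "adaptive_avg_pool2d",
    "upsample_bilinear",
    "softmax_cross_entropy",
    "SGD",
]


class Tensor:
    """A NumPy array plus a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward", "name")

    def __init__(self, data, requires_grad=False, _prev=(), name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._prev = tuple(_prev)
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def item(self):
        return float(self.data)


def _track(*parents):
    return tuple(p for p in parents if p.requires_grad or p._prev)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]                # N,C,oh,ow,kh,kw
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    xpad = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xpad[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    return xpad[:, :, pad:pad + h, pad:pad + w] if pad else xpad


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), weight layout (F, C, kh, kw)."""
    f, cin, kh, kw = w.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wf = w.data.reshape(f, -1)
    out = np.einsum("fk,nkl->nfl", wf, cols).reshape(x.shape[0], f, oh, ow)
    if b is not None:
        out += b.data[None, :, None, None]
    res = Tensor(out, _prev=_track(*( (x, w, b) if b is not None else (x, w))))

    def _backward(g):
        gl = g.reshape(g.shape[0], f, -1)
        if w.requires_grad or w._prev:
            w._accum(np.einsum("nfl,nkl->fk", gl, cols).reshape(w.shape))
        if b is not None and (b.requires_grad or b._prev):
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            dcols = np.einsum("fk,nfl->nkl", wf, gl)
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, pad))

    res._backward = _backward
    return res


# ---------------------------------------------------------------------------
# pointwise / structural ops


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    res = Tensor(x.data * mask, _prev=_track(x))

    def _backward(g):
        if x.requires_grad or x._prev:
            x._accum(g * mask)

    res._backward = _backward
    return res


def add(a: Tensor, b: Tensor) -> Tensor:
    res = Tensor(a.data + b.data, _prev=_track(a, b))

    def _backward(g):
        if a.requires_grad or a._prev:
            a._accum(g)
        if b.requires_grad or b._prev:
            b._accum(g)

    res._backward = _backward
    return res


def scale(x: Tensor, s: float) -> Tensor:
    res = Tensor(x.data * s, _prev=_track(x))

    def _backward(g):
        if x.requires_grad or x._prev:
            x._accum(g * s)

    res._backward = _backward
    return res


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    res = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=_track(*tensors))
    sizes = [t.shape[axis] for t in tensors]

    def _backward(g):
        off = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad or t._prev:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(off, off + s)
                t._accum(g[tuple(sl)])
            off += s

    res._backward = _backward
    return res


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization: deterministic, batch-size independent."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    xg = x.data.reshape(n, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xg - mu) * inv                                   # (n, g, m)
    xhat4 = xhat.reshape(n, c, h, w)
    out = gamma.data[None, :, None, None] * xhat4 + beta.data[None, :, None, None]
    res = Tensor(out, _prev=_track(x, gamma, beta))

    def _backward(g):
        if gamma.requires_grad or gamma._prev:
            gamma._accum((g * xhat4).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._prev:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            dxhat = (g * gamma.data[None, :, None, None]).reshape(n, groups, -1)
            m1 = dxhat.mean(axis=2, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=2, keepdims=True)
            dx = inv * (dxhat - m1 - xhat * m2)
            x._accum(dx.reshape(n, c, h, w))

    res._backward = _backward
    return res


def adaptive_avg_pool2d(x: Tensor, out_size: int) -> Tensor:
    """Average pooling to an ``out_size``×``out_size`` grid.

    Cell i spans rows [floor(i*H/b), ceil((i+1)*H/b)), so any b ≤ min(H, W)
    is valid even when it does not divide the input size.
    """
    n, c, h, w = x.shape
    b = out_size
    if b > min(h, w):
        raise ValueError(f"pooling grid {b} exceeds feature size {h}x{w}")
    hs = [(int(np.floor(i * h / b)), int(np.ceil((i + 1) * h / b))) for i in range(b)]
    ws = [(int(np.floor(j * w / b)), int(np.ceil((j + 1) * w / b))) for j in range(b)]
    out = np.empty((n, c, b, b))
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            out[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
    res = Tensor(out, _prev=_track(x))

    def _backward(g):
        if not (x.requires_grad or x._prev):
            return
        dx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += g[:, :, i:i + 1, j:j + 1] / area
        x._accum(dx)

    res._backward = _backward
    return res


def _interp_matrix(n_in: int, n_out: int, align_corners: bool) -> np.ndarray:
    """Row-stochastic (n_out, n_in) bilinear interpolation weights."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    for i in range(n_out):
        if align_corners and n_out > 1:
            src = i * (n_in - 1) / (n_out - 1)
        else:
            src = max(0.0, min(n_in - 1.0, (i + 0.5) * n_in / n_out - 0.5))
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        a[i, lo] += 1.0 - t
        a[i, hi] += t
    return a


def upsample_bilinear(x: Tensor, size: tuple[int, int], align_corners: bool = True) -> Tensor:
    """Bilinear resampling to ``size`` (corner-aligned by default).

    Separable: implemented as two matrix products, so the backward pass is
    exactly the transposed linear map.
    """
    h_out, w_out = size
    ah = _interp_matrix(x.shape[2], h_out, align_corners)
    aw = _interp_matrix(x.shape[3], w_out, align_corners)
    out = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw)
    res = Tensor(out, _prev=_track(x))

    def _backward(g):
        if x.requires_grad or x._prev:
            x._accum(np.einsum("oh,ncop,pw->nchw", ah, g, aw))

    res._backward = _backward
    return res


def softmax_cross_entropy(logits: Tensor, target: np.ndarray, ignore_label: int = 255) -> Tensor:
    """Mean per-pixel cross-entropy; pixels labelled ``ignore_label`` carry
    no loss and no gradient. ``target`` holds class *indices* (0..K-1)."""
    n, k, h, w = logits.shape
    tgt = np.asarray(target)
    valid = tgt != ignore_label
    n_valid = int(valid.sum())
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sm = ez / ez.sum(axis=1, keepdims=True)
    if n_valid == 0:
        res = Tensor(0.0, _prev=_track(logits))
        res._backward = lambda g: None
        return res
    ti = np.where(valid, tgt, 0)
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    picked = np.take_along_axis(logp, ti[:, None], axis=1)[:, 0]
    loss = -(picked * valid).sum() / n_valid
    res = Tensor(loss, _prev=_track(logits))

    def _backward(g):
        if not (logits.requires_grad or logits._prev):
            return
        grad = sm.copy()
        np.put_along_axis(grad, ti[:, None], np.take_along_axis(grad, ti[:, None], axis=1) - 1.0, axis=1)
        grad *= valid[:, None] / n_valid
        logits._accum(float(g) * grad)

    res._backward = _backward
    return res


# ---------------------------------------------------------------------------
# optimizer


class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
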