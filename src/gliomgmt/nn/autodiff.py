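"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the segmentation U-Net and the fusion
classifier need: 2-D convolution (same padding), 2x2 max pooling, nearest
2x upsampling, channel concatenation, dense layers, ReLU/sigmoid, dropout,
reductions, and a numerically stable binary cross-entropy on logits.

Arrays are laid out NHWC: (batch, height, width, channels).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """An array node in the computation graph.

    ``requires_grad`` marks trainable leaves; interior nodes accumulate
    gradients whenever any ancestor is trainable, which also makes
    activation gradients available to Grad-CAM.
    """

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad", "name")

    def __init__(self, data, parents=(), requires_grad=False, name=None):
        self.data = np.asarray(data)
        self.grad = None
        self._backward = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Backpropagate from this node through the whole graph."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    out._backward = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def bwd(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = bwd
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def bwd(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))

    def bwd(g):
        _accumulate(x, g * (x.data > 0))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                 np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    out = Tensor(s, (x,))

    def bwd(g):
        _accumulate(x, g * s * (1.0 - s))

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 convolution; x NHWC, w (kh, kw, cin, cout)."""
    kh, kw, cin, cout = w.data.shape
    ph, pw = kh // 2, kw // 2
    n, h, wd, _ = x.data.shape
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # (n, h, w, cin, kh, kw) -> (n, h, w, kh, kw, cin)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    cols2 = cols.reshape(n * h * wd, kh * kw * cin)
    wmat = w.data.reshape(kh * kw * cin, cout)
    out = Tensor((cols2 @ wmat + b.data).reshape(n, h, wd, cout), (x, w, b))

    def bwd(g):
        g2 = g.reshape(n * h * wd, cout)
        _accumulate(w, (cols2.T @ g2).reshape(w.data.shape))
        _accumulate(b, g2.sum(axis=0))
        dcols = (g2 @ wmat.T).reshape(n, h, wd, kh, kw, cin)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + h, j:j + wd, :] += dcols[:, :, :, i, j, :]
        _accumulate(x, dxp[:, ph:ph + h, pw:pw + wd, :])

    out._backward = bwd
    return out


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial dims, got {(h, w)}")
    r = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    r = np.ascontiguousarray(r).reshape(n, h // 2, w // 2, c, 4)
    idx = r.argmax(axis=-1)
    out = Tensor(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0], (x,))

    def bwd(g):
        dr = np.zeros_like(r)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dx = dr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        _accumulate(x, np.ascontiguousarray(dx).reshape(n, h, w, c))

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling."""
    n, h, w, c = x.data.shape
    out = Tensor(x.data.repeat(2, axis=1).repeat(2, axis=2), (x,))

    def bwd(g):
        _accumulate(x, g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))

    out._backward = bwd
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    out._backward = bwd
    return out


def mean(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(x.data.mean(axis=axis, keepdims=keepdims), (x,))
    count = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])

    def bwd(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        _accumulate(x, np.broadcast_to(g, x.data.shape) / count)

    out._backward = bwd
    return out


def sum_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), (x,))

    def bwd(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        _accumulate(x, np.broadcast_to(g, x.data.shape).copy())

    out._backward = bwd
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), (x,))

    def bwd(g):
        _accumulate(x, g.reshape(x.data.shape))

    out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout: scales kept units by 1/(1-rate) at train time."""
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    out = Tensor(x.data * mask, (x,))

    def bwd(g):
        _accumulate(x, g * mask)

    out._backward = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """NHWC -> (N, C) spatial mean."""
    return mean(x, axis=(1, 2))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed from logits.

    Uses log(1+exp(-|z|)) + max(z,0) - y*z, which never overflows.
    """
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    loss_el = np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - y * z
    out = Tensor(loss_el.mean(), (logits,))
    p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))

    def bwd(g):
        _accumulate(logits, g * (p - y) / y.size)

    out._backward = bwd
    return out


def soft_dice_loss(probs: Tensor, targets: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 - soft Dice over the whole batch (smooth eps keeps empty masks stable)."""
    t = as_tensor(np.asarray(targets, dtype=probs.data.dtype))
    inter = sum_(mul(probs, t))
    denom = add(sum_(probs), Tensor(float(np.asarray(targets).sum())))
    # dice = (2*inter + eps) / (denom + eps)
    num = add(mul(inter, Tensor(2.0)), Tensor(eps))
    den = add(denom, Tensor(eps))
    out = Tensor(1.0 - num.data / den.data, (num, den))

    def bwd(g):
        _accumulate(num, np.asarray(-g / den.data))
        _accumulate(den, np.asarray(g * num.data / den.data ** 2))

    out._backward = bwd
    return out
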