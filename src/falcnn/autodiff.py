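"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the feedback-attention ladder network needs:
3x3 same-padding convolution (im2col), 2x2 max pooling, factor-2 bilinear
upsampling, ReLU/sigmoid, channel concatenation, affine layers and a
softmax cross-entropy loss, plus SGD with momentum.  Everything is float32
and single-threaded numpy, so runs are bitwise reproducible.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self):
        """Accumulate gradients of self (summed to a scalar) into leaves."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g
            t._backward = None  # release closures (and im2col buffers) early
            if t is not self:
                t.grad = None

    def zero_grad(self):
        self.grad = None


def _make(data, parents, backward):
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, backward=backward)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------- elementwise

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return _make(out, (a, b),
                 lambda g: (_unbroadcast(g, a.data.shape),
                            _unbroadcast(g, b.data.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return _make(out, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.data.shape),
                            _unbroadcast(g * a.data, b.data.shape)))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _make(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = sigmoid_np(x.data)
    return _make(s, (x,), lambda g: (g * s * (1.0 - s),))


def sigmoid_np(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function on a plain array."""
    x = np.asarray(x, dtype=np.float32)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# -------------------------------------------------------------------- affine

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data
    return _make(out, (a, b),
                 lambda g: (g @ b.data.T, a.data.T @ g))


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x @ w.T + b  with x: (B, n_in), w: (n_out, n_in), b: (n_out,)."""
    out = x.data @ w.data.T + b.data

    def bwd(g):
        return g @ w.data, g.T @ x.data, g.sum(axis=0)

    return _make(out, (x, w, b), bwd)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    orig = x.data.shape
    return _make(x.data.reshape(shape), (x,), lambda g: (g.reshape(orig),))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tuple(tensors), bwd)


# --------------------------------------------------------------- convolution

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3 convolution, stride 1, zero padding 1 (spatial size preserved).

    x: (B, Cin, H, W); w: (Cout, Cin, 3, 3); b: (Cout,).
    """
    B, Cin, H, W = x.data.shape
    Cout = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # B,Cin,H,W,3,3
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(B, H * W, Cin * 9)
    wm = w.data.reshape(Cout, Cin * 9)
    out = cols @ wm.T + b.data  # (B, HW, Cout)
    out = out.transpose(0, 2, 1).reshape(B, Cout, H, W)

    def bwd(g):
        g2 = np.ascontiguousarray(g.reshape(B, Cout, H * W).transpose(0, 2, 1))
        gw = np.tensordot(g2, cols, axes=([0, 1], [0, 1])).reshape(w.data.shape)
        gb = g2.sum(axis=(0, 1))
        gcols = g2 @ wm                       # (B, HW, Cin*9)
        gwin = gcols.reshape(B, H, W, Cin, 3, 3)
        gxp = np.zeros_like(xp)
        for ki in range(3):
            for kj in range(3):
                gxp[:, :, ki:ki + H, kj:kj + W] += \
                    gwin[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return gxp[:, :, 1:H + 1, 1:W + 1], gw, gb

    return _make(out, (x, w, b), bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; gradient goes to a single argmax."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    xr = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 3, 5)
                              ).reshape(B, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gr.reshape(B, C, H, W),)

    return _make(out, (x,), bwd)


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense (n_out, n_in) bilinear interpolation operator, half-pixel centres."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    f = np.floor(src)
    t = src - f
    i0 = np.clip(f, 0, n_in - 1).astype(np.int64)
    i1 = np.clip(f + 1, 0, n_in - 1).astype(np.int64)
    A = np.zeros((n_out, n_in), dtype=np.float32)
    rows = np.arange(n_out)
    np.add.at(A, (rows, i0), (1.0 - t).astype(np.float32))
    np.add.at(A, (rows, i1), t.astype(np.float32))
    return A


_BILIN_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _bilin(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _BILIN_CACHE:
        _BILIN_CACHE[key] = _bilinear_matrix(n_out, n_in)
    return _BILIN_CACHE[key]


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling of (B, C, H, W); exact adjoint backward."""
    B, C, H, W = x.data.shape
    Ah = _bilin(2 * H, H)
    Aw = _bilin(2 * W, W)
    out = np.matmul(np.matmul(Ah, x.data), Aw.T)

    def bwd(g):
        return (np.matmul(Ah.T, np.matmul(g, Aw)),)

    return _make(out, (x,), bwd)


# --------------------------------------------------------------------- loss

def softmax_np(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class ids (B,)."""
    labels = np.asarray(labels)
    B = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logZ - z[np.arange(B), labels]))

    def bwd(g):
        p = softmax_np(logits.data, axis=1)
        p[np.arange(B), labels] -= 1.0
        return (g * p / B,)

    return _make(np.float32(loss), (logits,), bwd)


# ---------------------------------------------------------------- optimiser

class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: Sequence[Tensor], lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v


def kaiming_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He-normal initialisation suited to ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)
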