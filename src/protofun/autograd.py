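"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Provides exactly the operations the encoder/decoder networks need: dense
algebra (matmul, broadcast add/mul), pointwise nonlinearities (relu,
sigmoid, tanh, log, constant powers), valid-padding 3x3-style convolution,
overlapping max-pooling (pool 2, stride 1), reshape/concat/column slicing
and reductions.  Gradients are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

_LOG_EPS = 1e-12


class Tensor:
    """A numpy array plus gradient and the closure that back-propagates it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Back-propagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return scale(self, -1.0)

    def __sub__(self, other):
        return add(self, scale(_as_tensor(other), -1.0))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._parents):
        return
    g = g.astype(t.data.dtype, copy=False)
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale(a, k: float) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accum(a, g * k)

    return _make(a.data * k, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(out_data, (a, b), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    t = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - t * t))

    return _make(t, (a,), backward)


def log(a) -> Tensor:
    """Natural log with the argument clipped away from zero."""
    a = _as_tensor(a)
    clipped = np.maximum(a.data, _LOG_EPS)

    def backward(g):
        _accum(a, g / clipped)

    return _make(np.log(clipped), (a,), backward)


def pow_const(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data**exponent

    def backward(g):
        _accum(a, g * exponent * a.data ** (exponent - 1))

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def narrow(a, start: int, size: int, axis: int = 1) -> Tensor:
    """Contiguous slice along an axis."""
    a = _as_tensor(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + size)
    idx = tuple(idx)

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        _accum(a, full)

    return _make(a.data[idx], (a,), backward)


def mean(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size

    def backward(g):
        _accum(a, np.full_like(a.data, g / n))

    return _make(np.asarray(a.data.mean()), (a,), backward)


def tsum(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accum(a, np.full_like(a.data, g))

    return _make(np.asarray(a.data.sum()), (a,), backward)


def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid-padding cross-correlation: x (N,C,H,W), w (F,C,kh,kw)."""
    kh, kw = w.shape[2], w.shape[3]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: N,C,H',W',kh,kw -> N,H',W',C*kh*kw
    n, c, hh, ww = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * hh * ww, c * kh * kw)
    out = cols @ w.reshape(w.shape[0], -1).T
    return out.reshape(n, hh, ww, w.shape[0]).transpose(0, 3, 1, 2), cols


def conv2d(x, w, b) -> Tensor:
    """2-D convolution, stride 1, valid padding; bias per output channel."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    out_data, cols = _conv_valid(x.data, w.data)
    out_data = out_data + b.data[None, :, None, None]
    kh, kw = w.data.shape[2], w.data.shape[3]

    def backward(g):
        n, f, hh, ww = g.shape
        g_cols = g.transpose(0, 2, 3, 1).reshape(-1, f)
        _accum(b, g_cols.sum(axis=0))
        gw = g_cols.T @ cols  # F x C*kh*kw
        _accum(w, gw.reshape(w.data.shape))
        # dx = full-padding convolution of g with the rotated kernel
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        w_rot = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # C,F,kh,kw
        gx, _ = _conv_valid(gp, w_rot)
        _accum(x, gx)

    return _make(out_data, (x, w, b), backward)


def maxpool2(x) -> Tensor:
    """Max pooling with pool size 2 and stride 1 (overlapping windows)."""
    x = _as_tensor(x)
    win = np.lib.stride_tricks.sliding_window_view(x.data, (2, 2), axis=(2, 3))
    n, c, hh, ww = win.shape[:4]
    flat = win.reshape(n, c, hh, ww, 4)
    am = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]

    def backward(g):
        gx = np.zeros_like(x.data)
        ni, ci, ii, ji = np.indices(am.shape)
        np.add.at(gx, (ni, ci, ii + am // 2, ji + am % 2), g)
        _accum(x, gx)

    return _make(out_data, (x,), backward)


def focal_loss(logits: Tensor, targets: np.ndarray,
               gamma: float = 2.0, alpha: float = 0.25) -> Tensor:
    """Binary focal loss on logits, averaged over all entries.

    ``FL = -alpha * y * (1-p)^gamma * log p
           - (1-alpha) * (1-y) * p^gamma * log(1-p)``
    with ``p = sigmoid(logit)``.  At gamma=0, alpha=0.5 this is half the
    binary cross-entropy.
    """
    y = np.asarray(targets, dtype=logits.data.dtype)
    p = sigmoid(logits)
    one_minus_p = add(scale(p, -1.0), 1.0)
    pos = mul(mul(Tensor(y * -alpha), pow_const(one_minus_p, gamma)), log(p))
    neg = mul(mul(Tensor((1.0 - y) * -(1.0 - alpha)), pow_const(p, gamma)),
              log(one_minus_p))
    return mean(add(pos, neg))


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
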