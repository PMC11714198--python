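"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough tape machinery to train the hierarchical-interpolation
forecasting networks in this package: dense layers, ReLU, softplus,
max-pooling, concatenation, slicing and the scalar losses (MAE, Gaussian
negative log-likelihood, pinball).  Everything is float64 and
single-threaded, so training runs are bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "backward"]


class Tensor:
    """A numpy array plus the local backward rule that produced it."""

    __slots__ = ("data", "grad", "_parents", "_bwd")

    def __init__(self, data, parents=(), bwd=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._bwd = bwd

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(a.data + b.data, (a, b), bwd)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return Tensor(a.data - b.data, (a, b), bwd)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(a.data * b.data, (a, b), bwd)


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return Tensor(a.data / b.data, (a, b), bwd)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return Tensor(a.data @ b.data, (a, b), bwd)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0.0

    def bwd(g):
        _accum(a, g * mask)

    return Tensor(a.data * mask, (a,), bwd)


def softplus(a):
    """ln(1 + exp(x)), numerically stable for large |x|."""
    a = _as_tensor(a)
    x = a.data
    out = np.where(x > 30.0, x, np.log1p(np.exp(np.minimum(x, 30.0))))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))

    def bwd(g):
        _accum(a, g * sig)

    return Tensor(out, (a,), bwd)


def log(a):
    a = _as_tensor(a)

    def bwd(g):
        _accum(a, g / a.data)

    return Tensor(np.log(a.data), (a,), bwd)


def absval(a):
    a = _as_tensor(a)
    s = np.sign(a.data)

    def bwd(g):
        _accum(a, g * s)

    return Tensor(np.abs(a.data), (a,), bwd)


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tuple(tensors), bwd)


def col_slice(a, lo, hi):
    a = _as_tensor(a)

    def bwd(g):
        full = np.zeros_like(a.data)
        full[:, lo:hi] = g
        _accum(a, full)

    return Tensor(a.data[:, lo:hi], (a,), bwd)


def maxpool1d(a, kernel):
    """Non-overlapping max pooling along axis 1; ragged tail kept (ceil)."""
    a = _as_tensor(a)
    if kernel < 1:
        raise ValueError("pooling kernel must be >= 1")
    n, t = a.data.shape
    m = -(-t // kernel)  # ceil
    padded = np.full((n, m * kernel), -np.inf)
    padded[:, :t] = a.data
    reshaped = padded.reshape(n, m, kernel)
    idx = reshaped.argmax(axis=2)
    out = reshaped.max(axis=2)

    rows = np.repeat(np.arange(n), m)
    cols = (np.tile(np.arange(m), n) * kernel + idx.ravel())

    def bwd(g):
        full = np.zeros((n, m * kernel))
        np.add.at(full, (rows, cols), g.ravel())
        _accum(a, full[:, :t])

    return Tensor(out, (a,), bwd)


def mean(a):
    a = _as_tensor(a)
    size = a.data.size

    def bwd(g):
        _accum(a, np.full(a.data.shape, float(g) / size))

    return Tensor(a.data.mean(), (a,), bwd)


def backward(loss: Tensor) -> None:
    """Reverse-accumulate d(loss)/d(node) through the tape rooted at *loss*."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._bwd is not None and node.grad is not None:
            node._bwd(node.grad)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
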