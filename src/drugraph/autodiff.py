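"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just the operations the graph network needs: broadcast arithmetic, matrix
products, pointwise nonlinearities, reductions, row gather/scatter (segment
sums for message passing and graph readout), concatenation, slicing and a
fused softmax cross-entropy.  Gradients are accumulated by a topological
backward sweep; everything is float64 and single-threaded, so results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward(t.grad if t.grad is not None else np.zeros_like(t.data))
            if t._parents:
                # free the graph as we go: breaks the closure reference
                # cycles so memory stays bounded across many batches
                t.grad = None
                t._parents = ()
                t._backward = None

    # operator sugar ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return _slice(self, key)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient g back to the original operand shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    out._backward = back
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = back
    return out


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    out._backward = back
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def back(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = back
    return out


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data ** exponent, parents=(a,))

    def back(g):
        a._accum(g * exponent * a.data ** (exponent - 1.0))

    out._backward = back
    return out


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.exp(a.data), parents=(a,))

    def back(g):
        a._accum(g * out.data)

    out._backward = back
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def back(g):
        a._accum(g / a.data)

    out._backward = back
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.tanh(a.data), parents=(a,))

    def back(g):
        a._accum(g * (1.0 - out.data ** 2))

    out._backward = back
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))

    def back(g):
        a._accum(g * s * (1.0 - s))

    out._backward = back
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))

    def back(g):
        a._accum(g * (a.data > 0))

    out._backward = back
    return out


def maximum(a, b) -> Tensor:
    """Elementwise max; on ties the gradient routes to the first operand."""
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data >= b.data
    out = Tensor(np.where(mask, a.data, b.data), parents=(a, b))

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.shape))

    out._backward = back
    return out


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def back(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape).copy())

    out._backward = back
    return out


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def back(g):
        a._accum(g.reshape(a.shape))

    out._backward = back
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = back
    return out


def _slice(a, key) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data[key], parents=(a,))

    def back(g):
        full = np.zeros_like(a.data)
        full[key] = g  # basic slicing: no repeated indices
        a._accum(full)

    out._backward = back
    return out


def gather_rows(a, idx: np.ndarray) -> Tensor:
    """Rows a[idx]; indices may repeat (gradient scatter-adds)."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(a.data[idx], parents=(a,))

    def back(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    out._backward = back
    return out


def segment_sum(a, seg: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``n_segments`` buckets given per-row segment ids."""
    a = as_tensor(a)
    seg = np.asarray(seg, dtype=np.int64)
    shape = (n_segments,) + a.shape[1:]
    data = np.zeros(shape)
    np.add.at(data, seg, a.data)
    out = Tensor(data, parents=(a,))

    def back(g):
        a._accum(g[seg])

    out._backward = back
    return out


def segment_softmax(values, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a 1-D tensor within each segment.

    The per-segment maximum is subtracted as a constant for numerical
    stability; the softmax is invariant to that shift so gradients are exact.
    """
    v = as_tensor(values)
    seg = np.asarray(seg, dtype=np.int64)
    shift = np.full(n_segments, -np.inf)
    np.maximum.at(shift, seg, v.data)
    e = exp(v - Tensor(shift[seg]))
    denom = segment_sum(e, seg, n_segments)
    return e / gather_rows(denom, seg)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, C) logits against integer labels (fused)."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    losses = lse - z[np.arange(len(labels)), labels]
    out = Tensor(losses.mean(), parents=(logits,))

    def back(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(len(labels)), labels] -= 1.0
        logits._accum(g * p / len(labels))

    out._backward = back
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
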