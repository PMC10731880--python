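"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph pointer layer and the
classification head need: broadcast arithmetic, matmul, the usual
pointwise nonlinearities, reductions, concatenation, basic/advanced
indexing (with scatter-add backward), and a straight-through estimator
for hard discrete selection.

The tape is built eagerly; ``backward()`` walks it in reverse
topological order. Everything is float64 for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "straight_through", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, prev, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self._make(np.matmul(self.data, other.data), (self, other), None)
        a, b = self.data, other.data

        def backward(g):
            g = np.asarray(g)
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                    if a.ndim > 1 and g.ndim == a.ndim - 1:
                        ga = g[..., None] * b
                else:
                    ga = np.matmul(g, np.swapaxes(b, -1, -2))
                if a.ndim == 1 and ga.ndim > 1:
                    ga = ga.sum(axis=tuple(range(ga.ndim - 1)))
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g)
                elif b.ndim == 1:
                    gb = (np.swapaxes(a, -1, -2) @ g[..., None])[..., 0]
                    gb = gb.sum(axis=tuple(range(gb.ndim - 1))) if gb.ndim > 1 else gb
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- nonlinearities ----------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int):
        """Max along one axis; subgradient routed to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        y = np.max(self.data, axis=axis)
        out = self._make(y, (self,), None)
        shape = self.data.shape

        def backward(g):
            buf = np.zeros(shape)
            grid = np.indices(y.shape)
            key = list(grid)
            key.insert(axis if axis >= 0 else self.data.ndim + axis, idx)
            np.add.at(buf, tuple(key), np.asarray(g))
            self._accum(buf)

        out._backward = backward
        return out

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        orig = self.data.shape
        out._backward = lambda g: self._accum(np.asarray(g).reshape(orig))
        return out

    def __getitem__(self, key):
        out = self._make(self.data[key], (self,), None)
        shape = self.data.shape

        def backward(g):
            buf = np.zeros(shape)
            np.add.at(buf, key, np.asarray(g))
            self._accum(buf)

        out._backward = backward
        return out

    # -- composite ops -----------------------------------------------------
    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        y = shifted - logz
        out = self._make(y, (self,), None)
        sm = np.exp(y)

        def backward(g):
            g = np.asarray(g)
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    live = [t for t in tensors if t.requires_grad]
    if live:
        out.requires_grad = True
        out._prev = tuple(live)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    live = [t for t in tensors if t.requires_grad]
    if live:
        out.requires_grad = True
        out._prev = tuple(live)

        def backward(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(np.asarray(g), i, axis=axis))

        out._backward = backward
    return out


def straight_through(hard: Tensor, soft: Tensor) -> Tensor:
    """Forward value of `hard`, gradient of `soft` (straight-through)."""
    out = Tensor(hard.data.copy())
    if soft.requires_grad:
        out.requires_grad = True
        out._prev = (soft,)
        out._backward = lambda g: soft._accum(np.asarray(g))
    return out
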