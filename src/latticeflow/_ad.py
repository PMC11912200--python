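"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a deliberately small tape-based engine providing exactly the
operations the spline-coupling flow needs (broadcasted arithmetic, matmul,
tanh / exp / log / softplus / softmax, cumsum, gather along the last axis,
concatenation, slicing and reductions). Gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        # parents: tuple of (Tensor, vjp) where vjp maps the output cotangent
        # to this parent's cotangent contribution
        self._parents = tuple(parents)

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------
    def backward(self, seed: np.ndarray | None = None) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data) if seed is None else np.asarray(seed, dtype=float)
        for t in reversed(topo):
            if t.grad is None:
                continue
            for p, vjp in t._parents:
                g = vjp(t.grad)
                p.grad = g if p.grad is None else p.grad + g

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        o = _wrap(other)
        return Tensor(self.data + o.data,
                      [(self, lambda g: _unbroadcast(g, self.data.shape)),
                       (o, lambda g: _unbroadcast(g, o.data.shape))])

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        o = _wrap(other)
        return Tensor(self.data * o.data,
                      [(self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
                       (o, lambda g: _unbroadcast(g * self.data, o.data.shape))])

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _wrap(other)
        inv = 1.0 / o.data
        return Tensor(self.data * inv,
                      [(self, lambda g: _unbroadcast(g * inv, self.data.shape)),
                       (o, lambda g: _unbroadcast(-g * self.data * inv * inv, o.data.shape))])

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out
        return Tensor(self.data[idx], [(self, vjp)])

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), [(self, lambda g: g.reshape(old))])

    def sum(self, axis=None, keepdims=False):
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), [(self, vjp)])

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=float))


# ----------------------------------------------------------------------
# functions
# ----------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return Tensor(a.data @ b.data,
                  [(a, lambda g: g @ b.data.swapaxes(-1, -2)),
                   (b, lambda g: _unbroadcast(a.data.swapaxes(-1, -2) @ g, b.data.shape))])


def tanh(x: Tensor) -> Tensor:
    x = _wrap(x)
    y = np.tanh(x.data)
    return Tensor(y, [(x, lambda g: g * (1.0 - y * y))])


def sin(x: Tensor) -> Tensor:
    x = _wrap(x)
    return Tensor(np.sin(x.data), [(x, lambda g: g * np.cos(x.data))])


def exp(x: Tensor) -> Tensor:
    x = _wrap(x)
    y = np.exp(x.data)
    return Tensor(y, [(x, lambda g: g * y)])


def log(x: Tensor) -> Tensor:
    x = _wrap(x)
    return Tensor(np.log(x.data), [(x, lambda g: g / x.data)])


def softplus(x: Tensor) -> Tensor:
    x = _wrap(x)
    y = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(y, [(x, lambda g: g * sig)])


def softmax(x: Tensor) -> Tensor:
    """Softmax along the last axis."""
    x = _wrap(x)
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def vjp(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        return y * (g - dot)

    return Tensor(y, [(x, vjp)])


def cumsum_last(x: Tensor) -> Tensor:
    x = _wrap(x)

    def vjp(g):
        return np.flip(np.cumsum(np.flip(g, axis=-1), axis=-1), axis=-1)

    return Tensor(np.cumsum(x.data, axis=-1), [(x, vjp)])


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)

    def make_vjp(i):
        sl = [slice(None)] * data.ndim
        sl[axis if axis >= 0 else data.ndim + axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(data, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


def gather_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """``out[..., ] = x[..., idx[...]]`` picking one element along the last axis.

    ``idx`` has the shape of ``x`` minus its last axis; the selection is
    treated as constant (no gradient flows through the indices).
    """
    x = _wrap(x)
    idx = np.asarray(idx)
    taken = np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        out = np.zeros_like(x.data)
        np.put_along_axis(out, idx[..., None], g[..., None], axis=-1)
        return out

    return Tensor(taken, [(x, vjp)])


def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select with a constant boolean condition."""
    cond = np.asarray(cond, dtype=bool)
    a, b = _wrap(a), _wrap(b)
    return Tensor(np.where(cond, a.data, b.data),
                  [(a, lambda g: _unbroadcast(np.where(cond, g, 0.0), a.data.shape)),
                   (b, lambda g: _unbroadcast(np.where(cond, 0.0, g), b.data.shape))])
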