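"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed to express the log posteriors of the
hierarchical models in this package (Gaussian / Bernoulli / categorical
likelihoods, non-centred hierarchical blocks, tensor-product splines, and the
canonical-partial-correlation construction of LKJ-distributed correlation
matrices).  Gradients are accumulated on a tape and propagated with a single
reverse topological sweep.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# module-level tape: when active, Vars record themselves in creation order
# (which is a valid topological order), letting value_and_grad skip the DFS
_TAPE = None


class Var:
    """A node in the computation graph."""

    __slots__ = ("value", "parents", "vjps", "grad")

    # force numpy to defer to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, value, parents=(), vjps=()):
        if type(value) is not np.ndarray:
            value = np.asarray(value, dtype=float)
        self.value = value
        self.parents = parents
        self.vjps = vjps
        self.grad = None
        if _TAPE is not None:
            _TAPE.append(self)

    @property
    def shape(self):
        return self.value.shape

    # -- graph traversal ---------------------------------------------------

    def backward(self):
        """Reverse sweep; seeds with 1 (self must be scalar)."""
        order = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in order:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.grad is None:
                continue
            g = node.grad
            for parent, vjp in zip(node.parents, node.vjps):
                contrib = vjp(g)
                if parent.grad is None:
                    parent.grad = contrib.copy() if contrib is g else contrib
                else:
                    parent.grad = parent.grad + contrib

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, Var):
            return Var(self.value + other.value, (self, other),
                       (lambda g: _unbroadcast(g, self.value.shape),
                        lambda g: _unbroadcast(g, other.value.shape)))
        other = np.asarray(other, dtype=float)
        return Var(self.value + other, (self,),
                   (lambda g: _unbroadcast(g, self.value.shape),))

    __radd__ = __add__

    def __neg__(self):
        return Var(-self.value, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-other if isinstance(other, Var) else -np.asarray(other, dtype=float))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Var):
            return Var(self.value * other.value, (self, other),
                       (lambda g: _unbroadcast(g * other.value, self.value.shape),
                        lambda g: _unbroadcast(g * self.value, other.value.shape)))
        other = np.asarray(other, dtype=float)
        return Var(self.value * other, (self,),
                   (lambda g: _unbroadcast(g * other, self.value.shape),))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Var):
            return self * other ** -1.0
        other = np.asarray(other, dtype=float)
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        return self ** -1.0 * other

    def __pow__(self, exponent):
        assert not isinstance(exponent, Var)
        e = float(exponent)
        val = self.value ** e
        return Var(val, (self,),
                   (lambda g: _unbroadcast(g * e * self.value ** (e - 1.0),
                                           self.value.shape),))

    def __matmul__(self, other):
        if isinstance(other, Var):
            return Var(self.value @ other.value, (self, other),
                       (lambda g: _mm_grad_left(g, self.value, other.value),
                        lambda g: _mm_grad_right(g, self.value, other.value)))
        other = np.asarray(other, dtype=float)
        return Var(self.value @ other, (self,),
                   (lambda g: _mm_grad_left(g, self.value, other),))

    def __rmatmul__(self, other):
        other = np.asarray(other, dtype=float)
        return Var(other @ self.value, (self,),
                   (lambda g: _mm_grad_right(g, other, self.value),))

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        old = self.value.shape
        return Var(self.value.reshape(*shape), (self,),
                   (lambda g: g.reshape(old),))

    def slice(self, sl):
        """Basic slice of a 1-D leaf vector."""
        template = np.zeros_like(self.value)

        def vjp(g):
            out = np.zeros_like(template)
            out[sl] = g
            return out

        return Var(self.value[sl], (self,), (vjp,))

    def sum(self, axis=None):
        shape = self.value.shape

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            return np.broadcast_to(np.expand_dims(g, axis), shape).copy()

        return Var(self.value.sum(axis=axis), (self,), (vjp,))

    @property
    def T(self):
        return Var(self.value.T, (self,), (lambda g: g.T,))


def _mm_grad_left(g, a, b):
    if b.ndim == 1:
        if a.ndim == 1:
            return g * b
        return np.outer(g, b)
    if a.ndim == 1:
        return g @ b.T
    return g @ b.T


def _mm_grad_right(g, a, b):
    if a.ndim == 1:
        if b.ndim == 1:
            return g * a
        return np.outer(a, g)
    if b.ndim == 1:
        return a.T @ g
    return a.T @ g


# -- elementwise functions ----------------------------------------------------

def exp(x: Var) -> Var:
    val = np.exp(x.value)
    return Var(val, (x,), (lambda g: g * val,))


def log(x: Var) -> Var:
    return Var(np.log(x.value), (x,), (lambda g: g / x.value,))


def log1p(x: Var) -> Var:
    return Var(np.log1p(x.value), (x,), (lambda g: g / (1.0 + x.value),))


def tanh(x: Var) -> Var:
    val = np.tanh(x.value)
    return Var(val, (x,), (lambda g: g * (1.0 - val * val),))


def sqrt(x: Var) -> Var:
    val = np.sqrt(x.value)
    return Var(val, (x,), (lambda g: g * 0.5 / val,))


def log1pexp(x: Var) -> Var:
    """Numerically stable log(1 + exp(x))."""
    val = np.logaddexp(0.0, x.value)
    sig = 1.0 / (1.0 + np.exp(-x.value))
    return Var(val, (x,), (lambda g: g * sig,))


def gather(x: Var, idx) -> Var:
    """x[idx] along axis 0 with scatter-add backward."""
    idx = np.asarray(idx)
    shape = x.value.shape

    def vjp(g):
        out = np.zeros(shape)
        np.add.at(out, idx, g)
        return out

    return Var(x.value[idx], (x,), (vjp,))


def logsumexp(x: Var, axis: int) -> Var:
    m = np.max(x.value, axis=axis, keepdims=True)
    ex = np.exp(x.value - m)
    s = ex.sum(axis=axis)
    val = np.squeeze(m, axis=axis) + np.log(s)
    soft = ex / np.expand_dims(s, axis)

    def vjp(g):
        return np.expand_dims(g, axis) * soft

    return Var(val, (x,), (vjp,))


def cumsum(x: Var, axis: int) -> Var:
    def vjp(g):
        return np.flip(np.cumsum(np.flip(g, axis), axis=axis), axis)

    return Var(np.cumsum(x.value, axis=axis), (x,), (vjp,))


def stack(vars_, axis=0) -> Var:
    vals = np.stack([v.value for v in vars_], axis=axis)

    def make_vjp(i):
        return lambda g: np.take(g, i, axis=axis)

    return Var(vals, tuple(vars_), tuple(make_vjp(i) for i in range(len(vars_))))


def absolute(x: Var) -> Var:
    s = np.sign(x.value)
    return Var(np.abs(x.value), (x,), (lambda g: g * s,))


def sumsq(x: Var) -> Var:
    """sum(x**2) as a single fused node."""
    return Var(np.dot(x.value.ravel(), x.value.ravel()), (x,),
               (lambda g: (2.0 * g) * x.value,))


def neg_half_sumsq(x: Var) -> Var:
    """-0.5 * sum(x**2); the standard-normal log density kernel."""
    return Var(-0.5 * np.dot(x.value.ravel(), x.value.ravel()), (x,),
               (lambda g: (-g) * x.value,))


def value_and_grad(f):
    """Wrap f(Var leaf) -> scalar Var into g(ndarray) -> (float, ndarray)."""

    def wrapped(x: np.ndarray):
        global _TAPE
        prev = _TAPE
        _TAPE = tape = []
        try:
            leaf = Var(x)
            out = f(leaf)
        finally:
            _TAPE = prev
        out.grad = np.ones_like(out.value)
        for node in reversed(tape):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in zip(node.parents, node.vjps):
                contrib = vjp(g)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib
        g = leaf.grad
        if g is None:
            g = np.zeros_like(x)
        return float(out.value), g

    return wrapped
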