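"""Minimal reverse-mode automatic differentiation over numpy arrays.

All trainable parts of the package (encoders, loss functions, graph
aggregators) are expressed with :class:`Var` so a single backward pass
yields exact gradients.  The op set is deliberately small: the arithmetic
needed for linear/MLP encoders, cosine similarity and masked softmax
losses, nothing more.  Gradient correctness is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "as_var", "concat", "logsumexp", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation graph: a value plus a backward rule."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # ---- graph traversal -------------------------------------------------
    def backward(self):
        order, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        visit(self)
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_var(other)

        def bw(g):
            self.grad += _unbroadcast(g, self.shape)
            other.grad += _unbroadcast(g, other.shape)

        return Var(self.value + other.value, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self.grad += -g

        return Var(-self.value, (self,), bw)

    def __sub__(self, other):
        return self + (-as_var(other))

    def __rsub__(self, other):
        return as_var(other) + (-self)

    def __mul__(self, other):
        other = as_var(other)

        def bw(g):
            self.grad += _unbroadcast(g * other.value, self.shape)
            other.grad += _unbroadcast(g * self.value, other.shape)

        return Var(self.value * other.value, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_var(other)

        def bw(g):
            self.grad += _unbroadcast(g / other.value, self.shape)
            other.grad += _unbroadcast(-g * self.value / other.value**2, other.shape)

        return Var(self.value / other.value, (self, other), bw)

    def __rtruediv__(self, other):
        return as_var(other) / self

    def __matmul__(self, other):
        other = as_var(other)

        def bw(g):
            self.grad += g @ other.value.T
            other.grad += self.value.T @ g

        return Var(self.value @ other.value, (self, other), bw)

    @property
    def T(self):
        def bw(g):
            self.grad += g.T

        return Var(self.value.T, (self,), bw)

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_val = np.exp(self.value)

        def bw(g):
            self.grad += g * out_val

        return Var(out_val, (self,), bw)

    def log(self):
        def bw(g):
            self.grad += g / self.value

        return Var(np.log(self.value), (self,), bw)

    def sqrt(self):
        out_val = np.sqrt(self.value)

        def bw(g):
            self.grad += g / (2.0 * out_val)

        return Var(out_val, (self,), bw)

    def relu(self):
        mask = self.value > 0

        def bw(g):
            self.grad += g * mask

        return Var(self.value * mask, (self,), bw)

    def tanh(self):
        out_val = np.tanh(self.value)

        def bw(g):
            self.grad += g * (1.0 - out_val**2)

        return Var(out_val, (self,), bw)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self.grad += np.broadcast_to(g, self.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.shape)

        return Var(self.value.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self.grad += g.reshape(old)

        return Var(self.value.reshape(*shape), (self,), bw)

    def detach(self) -> np.ndarray:
        return self.value.copy()


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def concat(vars_, axis=0) -> Var:
    vars_ = [as_var(v) for v in vars_]
    sizes = [v.value.shape[axis] for v in vars_]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for v, a, b in zip(vars_, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            v.grad += g[tuple(sl)]

    return Var(np.concatenate([v.value for v in vars_], axis=axis), tuple(vars_), bw)


def logsumexp(x: Var, axis: int, keepdims: bool = False) -> Var:
    """Numerically stable logsumexp; the max shift is a constant, so the
    gradient is exact."""
    m = np.max(x.value, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)  # all-masked rows
    shifted = x + Var(-m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Var(m)
    if not keepdims:
        out = out.reshape(*np.squeeze(out.value, axis=axis).shape)
    return out


class Adam:
    """Adam optimizer over a dict of Vars (name -> parameter)."""

    def __init__(self, params: dict, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
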