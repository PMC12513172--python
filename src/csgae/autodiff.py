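"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the graph autoencoder's computation graph
needs: dense and sparse-constant matrix products, broadcast arithmetic,
relu/tanh/exp/log/sqrt, reductions, and row-wise helpers. Gradients follow
standard broadcasting rules (summed over broadcast axes). Backward is a
topological sweep over the recorded tape.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "spmm", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- ops ---------------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._make(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g / b.data, a.shape))
            b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return self._make(a.data / b.data, (a, b), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), bw)

    @property
    def T(self):
        a = self
        return self._make(a.data.T, (a,), lambda g: a._accumulate(g.T))

    def relu(self):
        a = self
        pos = a.data > 0
        return self._make(a.data * pos, (a,), lambda g: a._accumulate(g * pos))

    def tanh(self):
        a = self
        y = np.tanh(a.data)
        return self._make(y, (a,), lambda g: a._accumulate(g * (1 - y**2)))

    def exp(self):
        a = self
        y = np.exp(a.data)
        return self._make(y, (a,), lambda g: a._accumulate(g * y))

    def log(self):
        a = self
        return self._make(np.log(a.data), (a,), lambda g: a._accumulate(g / a.data))

    def sqrt(self):
        a = self
        y = np.sqrt(a.data)
        return self._make(y, (a,), lambda g: a._accumulate(g / (2.0 * y)))

    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def row_normalize(self, eps: float = 0.0):
        """Rows scaled to unit Euclidean norm (cosine-similarity prep)."""
        norms = (self * self).sum(axis=1, keepdims=True).sqrt()
        if eps:
            norms = norms + eps
        return self / norms


def spmm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a tensor; grad flows to ``x``."""
    A = A.tocsr()
    AT = A.T.tocsr()

    def bw(g):
        x._accumulate(AT @ g)

    out = Tensor(A @ x.data)
    if x.requires_grad or x._parents:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = bw
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
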