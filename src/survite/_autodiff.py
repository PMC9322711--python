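"""Minimal reverse-mode automatic differentiation over numpy arrays.

The estimator needs gradients of a composite objective (censored absolute /
hinge errors, an RBF-kernel MMD between representation samples, a softmax
cross-entropy and several hinge-type constraint penalties) with respect to the
weights of eight small fully connected networks.  The engine below supports
exactly the primitives those losses are built from: broadcasting arithmetic,
matrix products, reductions, concatenation, row selection and the elementwise
nonlinearities used by the networks (leaky ReLU, tanh, exp, log, sqrt, abs,
positive-part).  Gradients are accumulated by a topological backward sweep.

Every primitive is exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsumexp", "scatter_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading axes numpy added
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      parents=parents if req else (),
                      backward=backward if req else None)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / (2.0 * out_data))

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bw)

    def abs(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bw)

    def relu(self):
        """Positive part max(0, x); subgradient 0 at the kink."""

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(np.maximum(self.data, 0.0), (self,), bw)

    def leaky_relu(self, slope: float = 0.01):
        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, slope))

        return self._make(np.where(self.data > 0, self.data, slope * self.data),
                          (self,), bw)

    # -- shape ops ------------------------------------------------------------
    def take_rows(self, index):
        """Select rows by integer or boolean index along axis 0."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accum(full)

        return self._make(self.data[index], (self,), bw)

    def take_cols(self, j: int):
        """Select one column along axis 1, returning a 1-D tensor."""

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, j] = g
                self._accum(full)

        return self._make(self.data[:, j], (self,), bw)

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    return Tensor(data, requires_grad=req,
                  parents=tuple(tensors) if req else (),
                  backward=bw if req else None)


def scatter_rows(values: Tensor, index, n: int) -> Tensor:
    """Place ``values`` at ``index`` in a zero vector of length ``n``."""
    index = np.asarray(index)
    if index.dtype == bool:
        index = np.flatnonzero(index)

    def bw(g):
        if values.requires_grad:
            values._accum(g[index])

    data = np.zeros(n) if values.data.ndim == 1 else \
        np.zeros((n,) + values.data.shape[1:])
    data[index] = values.data
    return Tensor(data, requires_grad=values.requires_grad,
                  parents=(values,) if values.requires_grad else (),
                  backward=bw if values.requires_grad else None)


def logsumexp(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable log-sum-exp; the max shift is treated as constant."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(shift)
    return (shifted.exp().sum(axis=axis, keepdims=True)).log() + Tensor(shift)
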