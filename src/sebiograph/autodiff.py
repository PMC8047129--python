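"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a float64
numpy array and remembers how it was produced, so a single call to
:meth:`Tensor.backward` on a scalar loss accumulates ``grad`` on every
parameter that fed into it.  The op set is exactly what the graph model
needs — dense matmul, broadcasting arithmetic, the usual pointwise
nonlinearities, axis reductions (including a subgradient max used by the
pooling layers) and a numerically stabilized log-sum-exp.

Gradients are plain float64 numpy arrays.  Broadcasting in the forward pass
is undone in the backward pass by summing over the broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "stack",
    "logsumexp",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # Leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Axes of size 1 that were stretched.
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in _parents)
        )
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basic introspection -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph construction helpers ------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        p = float(p)
        out = Tensor(self.data ** p, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            g = np.asarray(g)
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 2:  # (k,) @ (k,n) -> (n,)
                    self._accumulate(b @ g)
                elif a.ndim == 2 and b.ndim == 1:  # (m,k) @ (k,) -> (m,)
                    self._accumulate(np.outer(g, b))
                elif a.ndim == 1 and b.ndim == 1:  # inner product
                    self._accumulate(g * b)
                else:
                    self._accumulate(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 2:
                    other._accumulate(np.outer(a, g))
                elif a.ndim == 2 and b.ndim == 1:
                    other._accumulate(a.T @ g)
                elif a.ndim == 1 and b.ndim == 1:
                    other._accumulate(g * a)
                else:
                    other._accumulate(a.T @ g)

        out._backward = bwd
        return out

    # -- pointwise nonlinearities ----------------------------------------------

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / self.data
        )
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - val * val)
        )
        return out

    def sigmoid(self) -> "Tensor":
        # Stable for large |x|.
        val = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * val * (1.0 - val)
        )
        return out

    # -- reductions ------------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        val = self.data.max(axis=axis, keepdims=True)
        # Subgradient: ties share the incoming gradient equally.
        mask = (self.data == val).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        out = Tensor(val if keepdims else np.squeeze(val, axis), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(g * mask)

        out._backward = bwd
        return out

    # -- shape manipulation ------------------------------------------------------

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            np.asarray(g).T
        )
        return out

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            np.asarray(g).reshape(self.data.shape)
        )
        return out

    def take_rows(self, idx) -> "Tensor":
        """Select rows (axis 0) by an integer index array."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, np.asarray(g))
            self._accumulate(full)

        out._backward = bwd
        return out

    # -- backward pass ------------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(parts: Iterable[Tensor], axis: int = 0) -> Tensor:
    parts = [Tensor._lift(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _parents=parts)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        g = np.asarray(g)
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(parts: Iterable[Tensor], axis: int = 0) -> Tensor:
    parts = [Tensor._lift(p) for p in parts]
    out = Tensor(np.stack([p.data for p in parts], axis=axis), _parents=parts)

    def bwd(g):
        g = np.asarray(g)
        for i, p in enumerate(parts):
            if p.requires_grad:
                p._accumulate(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log(sum(exp(x))) along ``axis``."""
    m = x.data.max(axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(np.squeeze(out.data, axis=axis).shape)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    ax = axis if axis >= 0 else x.ndim + axis
    return (x - logsumexp(x, axis=ax, keepdims=True)).exp()
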