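"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training losses used in this package (cross-entropy with soft targets,
neighbour-consistency divergences) need exact gradients with respect to both
the network logits and the hidden representations that feed the neighbour
similarity graph.  This module provides a small tape-based tensor type that
covers exactly the operations those losses are built from.  All arithmetic is
float64; graphs are rebuilt on every forward pass and freed after
``backward``.

Only scalar-valued roots are differentiated (``backward`` is called on the
loss).  Broadcasting follows numpy semantics; gradients of broadcast operands
are summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "stack", "relu", "sigmoid", "log", "exp", "sqrt", "clip"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were added or broadcast relative to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- helpers ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ---------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from a scalar root, accumulating ``grad`` on leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:  # inner product
                self._accum(g * b)
                other._accum(g * a)
            elif a.ndim == 2 and b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            elif a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            else:
                self._accum(g @ b.T)
                other._accum(a.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    @property
    def T(self) -> "Tensor":
        def bwd(g):
            self._accum(g.T)

        return Tensor(self.data.T, parents=(self,), backward=bwd)

    # -- reductions & reshaping ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)


# -- elementwise functions -------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accum(g * mask)

    return Tensor(np.where(mask, x.data, 0.0), parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accum(g * out * (1.0 - out))

    return Tensor(out, parents=(x,), backward=bwd)


def log(x: Tensor) -> Tensor:
    def bwd(g):
        x._accum(g / x.data)

    return Tensor(np.log(x.data), parents=(x,), backward=bwd)


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)

    def bwd(g):
        x._accum(g * out)

    return Tensor(out, parents=(x,), backward=bwd)


def sqrt(x: Tensor) -> Tensor:
    out = np.sqrt(x.data)

    def bwd(g):
        x._accum(g * 0.5 / out)

    return Tensor(out, parents=(x,), backward=bwd)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values to [lo, hi]; the gradient is passed only inside the interval."""
    mask = (x.data > lo) & (x.data < hi)

    def bwd(g):
        x._accum(g * mask)

    return Tensor(np.clip(x.data, lo, hi), parents=(x,), backward=bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )
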