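"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core shared by the LSTM evidence bank and the
trainable evidence-combination network.  A :class:`Tensor` wraps an
ndarray, records the operations that produced it, and :meth:`Tensor.backward`
accumulates gradients by reverse topological traversal.  Only the operations
those two models need are implemented: elementwise arithmetic with
broadcasting, matrix multiplication, slicing, reductions, and the smooth
nonlinearities (sigmoid, tanh, exp, log) plus a lower clamp used to guard
logarithms.

The engine is deliberately eager and graph-per-call: every forward pass
builds a fresh graph, so there is no state to reset between steps.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "exp", "log", "clamp_min", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        value,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        o = self._lift(other)
        out = Tensor(self.value + o.value, (self, o))

        def bwd(g):
            self._accum(g)
            o._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        o = self._lift(other)
        out = Tensor(self.value * o.value, (self, o))

        def bwd(g):
            self._accum(g * o.value)
            o._accum(g * self.value)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        out = Tensor(self.value / o.value, (self, o))

        def bwd(g):
            self._accum(g / o.value)
            o._accum(-g * self.value / (o.value * o.value))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.value**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.value ** (p - 1))
        return out

    def __matmul__(self, other):
        o = self._lift(other)
        out = Tensor(self.value @ o.value, (self, o))

        def bwd(g):
            self._accum(g @ o.value.T)
            o._accum(self.value.T @ g)

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], (self,))

        def bwd(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- backward --------------------------------------------------------

    def backward(self) -> None:
        """Accumulate d(self)/d(leaf) into every ``requires_grad`` leaf."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs from long LSTM rollouts are deep
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- pointwise nonlinearities --------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.value))
    out = Tensor(s, (x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.value)
    out = Tensor(t, (x,))
    out._backward = lambda g: x._accum(g * (1.0 - t * t))
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.value)
    out = Tensor(e, (x,))
    out._backward = lambda g: x._accum(g * e)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.value), (x,))
    out._backward = lambda g: x._accum(g / x.value)
    return out


def clamp_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo); gradient is passed only where x > lo."""
    mask = x.value > lo
    out = Tensor(np.where(mask, x.value, lo), (x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    vals = [t.value for t in tensors]
    out = Tensor(np.concatenate(vals, axis=axis), tuple(tensors))
    sizes = [v.shape[axis] for v in vals]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out
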