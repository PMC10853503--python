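"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based engine providing exactly the operations the hierarchical
multi-[cls]-token transformer and its self-distillation loop need: broadcasted
arithmetic, batched matmul, reshapes, reductions, stable (log-)softmax, GELU
and concatenation. Gradients accumulate into ``Tensor.grad`` after calling
``backward()`` on a scalar.

Design notes
------------
* Arrays are float64 by default; training code passes float32 for speed.
* Broadcasting is handled by summing gradients over broadcast axes
  (``_unbroadcast``), mirroring NumPy semantics.
* The graph is a DAG of ``Tensor`` nodes; ``backward`` runs a topological
  sort. There is no graph reuse: each forward pass builds a fresh tape.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "matmul", "softmax", "log_softmax", "gelu"]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion limits
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        data = self.data + other.data
        return self._node(
            data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        data = self.data * other.data
        return self._node(
            data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        data = self.data / other.data
        return self._node(
            data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        data = self.data**p
        return self._node(data, (self,), lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other):
        return matmul(self, other)

    # --------------------------------------------------------------- elemwise
    def exp(self):
        data = np.exp(self.data)
        return self._node(data, (self,), lambda g: (g * data,))

    def log(self):
        return self._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        data = np.sqrt(self.data)
        return self._node(data, (self,), lambda g: (g * 0.5 / data,))

    # ------------------------------------------------------------ shape moves
    def reshape(self, shape):
        old = self.shape
        return self._node(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        return self._node(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swap_last2(self):
        """Transpose the trailing two axes (batched matrix transpose)."""
        axes = tuple(range(self.ndim - 2)) + (self.ndim - 1, self.ndim - 2)
        return self.transpose(axes)

    def broadcast_to(self, shape):
        old = self.shape
        return self._node(
            np.broadcast_to(self.data, shape).copy(),
            (self,),
            lambda g: (_unbroadcast(g, old),),
        )

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        return self._node(data, (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._node(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis=None, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            expanded = data if keepdims or axis is None else np.expand_dims(data, axis)
            mask = (self.data == expanded).astype(self.data.dtype)
            mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            return (mask * gg,)

        return self._node(data, (self,), backward)


# -------------------------------------------------------------- free functions
def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        # collapse broadcast batch dims back to parameter shapes
        return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

    return Tensor._node(data, (a, b), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._wrap(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return ((g - dot) * y,)

    return Tensor._node(y, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._wrap(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse
    sm = np.exp(out)

    def backward(g):
        return (g - sm * g.sum(axis=axis, keepdims=True),)

    return Tensor._node(out, (x,), backward)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = Tensor._wrap(x)
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    data = x.data * cdf

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data**2)
        return (g * (cdf + x.data * pdf),)

    return Tensor._node(data, (x,), backward)
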