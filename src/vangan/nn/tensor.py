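"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style, extended to n-d arrays
with broadcasting, reductions and the handful of structured operations
(3-D convolution, pooling, padding) needed by the volumetric networks in
this package.  Float32 is the working precision for network tensors;
float64 inputs are preserved, which the finite-difference gradient checks
rely on.
"""
from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "minimum", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph.

    Gradients are accumulated on leaf tensors (those created with
    ``requires_grad=True``); intermediate nodes only route gradients.
    Subgraphs whose inputs do not require gradients are dropped at
    construction time, so wrapping raw data in a fresh ``Tensor`` acts as
    a detach.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = ()):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents: Tuple["Tensor", ...] = (
            tuple(parents) if self.requires_grad else ())
        self._backward: Optional[Callable[[np.ndarray], tuple]] = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph engine --------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that has no graph")
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        flowing: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = flowing.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                key = id(p)
                if key in flowing:
                    flowing[key] = flowing[key] + pg
                else:
                    flowing[key] = pg

    # -- elementwise arithmetic ---------------------------------------
    def __add__(self, other):
        other = _ensure(other)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            sa, sb = self.data.shape, other.data.shape
            out._backward = lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb))
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _ensure(other)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            a, b = self.data, other.data
            out._backward = lambda g: (_unbroadcast(g * b, a.shape),
                                       _unbroadcast(g * a, b.shape))
        return out

    __rmul__ = __mul__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_ensure(other))

    def __rsub__(self, other):
        return _ensure(other) + (-self)

    def __truediv__(self, other):
        other = _ensure(other)
        out = _node(self.data / other.data, (self, other))
        if out.requires_grad:
            a, b = self.data, other.data
            out._backward = lambda g: (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape))
        return out

    def __rtruediv__(self, other):
        return _ensure(other) / self

    def __pow__(self, exponent: float):
        p = float(exponent)
        out = _node(self.data ** p, (self,))
        if out.requires_grad:
            a = self.data
            out._backward = lambda g: (g * p * a ** (p - 1.0),)
        return out

    # -- elementwise functions ----------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = _node(e, (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out.requires_grad:
            a = self.data
            out._backward = lambda g: (g / a,)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = _node(r, (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * 0.5 / r,)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = _node(t, (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * (1.0 - t * t),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def relu(self):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, 0.0), (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * mask,)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, slope * self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * np.where(mask, 1.0, slope),)
        return out

    def abs(self):
        s = np.sign(self.data)
        out = _node(np.abs(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * s,)
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        out = _node(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            out._backward = lambda g: (g * mask,)
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape

            def bw(g):
                if axis is None:
                    return (np.broadcast_to(g, shape).copy(),)
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % len(shape) for a in axes):
                        gg = np.expand_dims(gg, ax)
                return (np.broadcast_to(gg, shape).copy(),)

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in
             (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation -------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            orig = self.data.shape
            out._backward = lambda g: (g.reshape(orig),)
        return out

    def transpose(self, axes):
        out = _node(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            shape = self.data.shape

            def bw(g):
                full = np.zeros(shape, dtype=g.dtype)
                np.add.at(full, idx, g)
                return (full,)

            out._backward = bw
        return out

    def __matmul__(self, other):
        other = _ensure(other)
        out = _node(self.data @ other.data, (self, other))
        if out.requires_grad:
            a, b = self.data, other.data
            out._backward = lambda g: (g @ b.T, a.T @ g)
        return out


def _ensure(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    return Tensor(data, parents=parents)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise minimum; gradient routes to the smaller input (ties -> a)."""
    a, b = _ensure(a), _ensure(b)
    take_a = a.data <= b.data
    out = _node(np.where(take_a, a.data, b.data), (a, b))
    if out.requires_grad:
        out._backward = lambda g: (
            _unbroadcast(g * take_a, a.data.shape),
            _unbroadcast(g * ~take_a, b.data.shape))
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    take_a = a.data >= b.data
    out = _node(np.where(take_a, a.data, b.data), (a, b))
    if out.requires_grad:
        out._backward = lambda g: (
            _unbroadcast(g * take_a, a.data.shape),
            _unbroadcast(g * ~take_a, b.data.shape))
    return out

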