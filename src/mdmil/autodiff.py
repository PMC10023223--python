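"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in this package is small (a handful of linear maps, layer norms
and attention softmaxes per forward pass), so a compact tape-based
autodiff is sufficient and keeps the package free of deep-learning
framework dependencies. All arithmetic is float64.

Only the primitives the architecture needs are implemented: broadcasted
elementwise ops, (batched) matmul, exp/log/erf, axis reductions
(sum/max), row gathering, reshape/transpose, and a fused softmax.
Gradient correctness is validated against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "as_tensor", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation graph: a float64 array plus a backward rule."""

    __slots__ = ("data", "grad", "_parents", "_vjps")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        vjps: Sequence[Callable[[np.ndarray], np.ndarray]] = (),
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._vjps = tuple(vjps)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------------ #
    # graph construction

    def __add__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.data + o.data,
            (self, o),
            (
                lambda g: _unbroadcast(g, self.data.shape),
                lambda g: _unbroadcast(g, o.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.data * o.data,
            (self, o),
            (
                lambda g: _unbroadcast(g * o.data, self.data.shape),
                lambda g: _unbroadcast(g * self.data, o.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.data / o.data,
            (self, o),
            (
                lambda g: _unbroadcast(g / o.data, self.data.shape),
                lambda g: _unbroadcast(-g * self.data / (o.data**2), o.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        return Tensor(
            self.data**p,
            (self,),
            (lambda g: g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.data @ o.data,
            (self, o),
            (
                lambda g: _unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.data.shape),
                lambda g: _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.data.shape),
            ),
        )

    # ------------------------------------------------------------------ #
    # shape ops

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(self.data.reshape(shape), (self,), (lambda g: g.reshape(old),))

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor(
            np.transpose(self.data, axes),
            (self,),
            (lambda g: np.transpose(g, inv),),
        )

    def take_rows(self, indices) -> "Tensor":
        """Gather rows (axis 0); gradient scatters back with accumulation."""
        idx = np.asarray(indices)

        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], (self,), (vjp,))

    # ------------------------------------------------------------------ #
    # reductions / nonlinearities

    def sum(self, axis=None, keepdims=False):
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), (vjp,))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims=False):
        out = self.data.max(axis=axis, keepdims=True)

        def vjp(g):
            mask = self.data == out
            mask = mask / mask.sum(axis=axis, keepdims=True)  # split among ties
            gg = g if (keepdims or axis is None) else np.expand_dims(g, axis)
            return mask * gg

        val = out if keepdims else np.squeeze(out, axis=axis) if axis is not None else out.item()
        return Tensor(val, (self,), (vjp,))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, (self,), (lambda g: g * out,))

    def log(self):
        return Tensor(np.log(self.data), (self,), (lambda g: g / self.data,))

    def erf(self):
        return Tensor(
            _sp.erf(self.data),
            (self,),
            (lambda g: g * 2.0 / np.sqrt(np.pi) * np.exp(-self.data**2),),
        )

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, (self,), (lambda g: g * mask,))

    def softmax(self, axis=-1):
        """Numerically stable softmax along `axis` (fused primitive)."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def vjp(g):
            return s * (g - (g * s).sum(axis=axis, keepdims=True))

        return Tensor(s, (self,), (vjp,))

    # ------------------------------------------------------------------ #
    # backward

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                g = vjp(node.grad)
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """A leaf that participates in the graph but whose grad is discarded."""
    return Tensor(np.asarray(x, dtype=np.float64))
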