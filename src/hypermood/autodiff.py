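"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the mood-regression models need: broadcasted
arithmetic, (batched) matrix products, ReLU/GeLU/tanh/erf, softmax, reductions,
shape manipulation, concatenation and basic indexing. Gradients are accumulated
by a topological-order backward sweep. Everything is float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat", "relu", "gelu", "softmax", "sqrt", "exp", "tanh"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data ** p, (a,), lambda g: a._accum(g * p * a.data ** (p - 1))
        )

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        out = a.data @ b.data

        def bw(g):
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

        return Tensor._make(out, (a, b), bw)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(a.data.shape))
        )

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def swapaxes(self, ax1, ax2):
        a = self
        return Tensor._make(
            np.swapaxes(a.data, ax1, ax2),
            (a,),
            lambda g: a._accum(np.swapaxes(g, ax1, ax2)),
        )

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bw)


# -- free functions ----------------------------------------------------------


def concat(tensors, axis=-1):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def relu(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    mask = x.data > 0
    return Tensor._make(x.data * mask, (x,), lambda g: x._accum(g * mask))


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error GeLU: x * Phi(x)."""
    x = Tensor.as_tensor(x)
    cdf = 0.5 * (1.0 + _erf(x.data * _INV_SQRT2))
    pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data ** 2)
    return Tensor._make(
        x.data * cdf, (x,), lambda g: x._accum(g * (cdf + x.data * pdf))
    )


def tanh(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    y = np.tanh(x.data)
    return Tensor._make(y, (x,), lambda g: x._accum(g * (1.0 - y ** 2)))


def exp(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    y = np.exp(x.data)
    return Tensor._make(y, (x,), lambda g: x._accum(g * y))


def sqrt(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    y = np.sqrt(x.data)
    return Tensor._make(y, (x,), lambda g: x._accum(g * 0.5 / y))


def softmax(x: Tensor, axis=-1) -> Tensor:
    x = Tensor.as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor._make(y, (x,), bw)
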