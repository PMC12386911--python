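"""Reverse-mode automatic differentiation over numpy arrays.

This is the package's compute core: a small tape-based tensor engine with
exactly the operations the detection network needs (2-D convolution with
channel groups, batch normalisation, elementwise nonlinearities, reductions,
concatenation, nearest-neighbour upsampling).  All arithmetic is float32
unless a caller passes float64 explicitly.

Gradients follow the usual conventions: ``backward()`` on a scalar tensor
performs a topological sweep and accumulates ``.grad`` on every tensor
created with ``requires_grad=True`` (and on intermediates that need it).
Broadcasting in binary ops is supported; gradients are summed back over the
broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "where_positive"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make numpy defer to the reflected operators instead of building
    # object arrays when an ndarray is the left operand
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype != np.float64 else np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _wrap(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        data = fwd(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        return Tensor._wrap(data, (self, other), backward)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor(np.asarray(other, dtype=self.data.dtype)) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._wrap(data, (self,), backward)

    # -- elementwise functions --------------------------------------------
    def _unary(self, fwd, dfwd):
        data = fwd(self.data)

        def backward(g):
            self._accum(g * dfwd(self.data, data))

        return Tensor._wrap(data, (self,), backward)

    def exp(self):
        return self._unary(np.exp, lambda x, y: y)

    def log(self):
        return self._unary(np.log, lambda x, y: 1.0 / x)

    def sqrt(self):
        return self._unary(np.sqrt, lambda x, y: 0.5 / y)

    def arctan(self):
        return self._unary(np.arctan, lambda x, y: 1.0 / (1.0 + x * x))

    def sigmoid(self):
        def fwd(x):
            z = np.exp(-np.abs(x))
            return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))

        return self._unary(fwd, lambda x, y: y * (1.0 - y))

    def tanh(self):
        return self._unary(np.tanh, lambda x, y: 1.0 - y * y)

    def relu(self):
        return self._unary(lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(x.dtype))

    def silu(self):
        """x * sigmoid(x); the default conv-block activation."""
        return self * self.sigmoid()

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        c = np.sqrt(2.0 / np.pi).astype(np.float32)
        inner = (self + (self ** 3) * 0.044715) * float(c)
        return self * 0.5 * (inner.tanh() + 1.0)

    def clamp_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo (subgradient 0 at the clamp)."""
        data = np.maximum(self.data, lo)

        def backward(g):
            self._accum(g * (self.data > lo))

        return Tensor._wrap(data, (self,), backward)

    def clamp_max(self, hi: float):
        data = np.minimum(self.data, hi)

        def backward(g):
            self._accum(g * (self.data < hi))

        return Tensor._wrap(data, (self,), backward)

    def minimum(self, other: "Tensor"):
        return self._binary(other, np.minimum,
                            lambda g, a, b: g * (a <= b),
                            lambda g, a, b: g * (b < a))

    def maximum(self, other: "Tensor"):
        return self._binary(other, np.maximum,
                            lambda g, a, b: g * (a >= b),
                            lambda g, a, b: g * (b > a))

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._wrap(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        data = self.data.reshape(*shape)
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._wrap(data, (self,), backward)

    def transpose(self, axes):
        data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._wrap(data, (self,), backward)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._wrap(data, (self,), backward)


def concat(tensors: list, axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._wrap(data, tuple(tensors), backward)


def where_positive(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select a where cond > 0 else b; cond is a plain array (no gradient)."""
    mask = (np.asarray(cond) > 0)
    data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return Tensor._wrap(data, (a, b), backward)
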