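"""Minimal reverse-mode autograd over numpy arrays.

The detector graphs in this package need only a small, fixed vocabulary of
differentiable array operations (convolution, pooling, interpolation,
elementwise nonlinearities, reductions, reshapes and batched matmul).  This
module implements exactly that vocabulary as a tape-based autograd: every op
returns a new :class:`Tensor` holding a closure that scatters the upstream
gradient back to its inputs.  Gradients are accumulated with ``+=`` semantics,
so shared sub-expressions (residual connections, CSP splits) are handled
naturally.

Arrays keep whatever float dtype they were created with; float32 is the
default for model weights, while the finite-difference tests use float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x, dtype=None):
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    a = np.asarray(x)
    if dtype is None and a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    elif dtype is not None:
        a = a.astype(dtype)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data.item())

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray, own: bool = False):
        """Accumulate gradient ``g`` into ``t``.

        ``own=True`` promises that ``g`` is a freshly allocated array no one
        else will touch, letting us adopt it without a defensive copy.
        """
        if t.requires_grad:
            if t.grad is None:
                if (
                    own
                    and g.dtype == t.data.dtype
                    and g.base is None
                    and g.flags.writeable
                ):
                    t.grad = g
                else:
                    t.grad = np.array(g, dtype=t.data.dtype)
            else:
                t.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -----------------------------------------
    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            Tensor._accum(self, _unbroadcast(g, self.data.shape))
            Tensor._accum(other, _unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            Tensor._accum(self, -g, own=True)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            if self.requires_grad:
                Tensor._accum(self, _unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad:
                Tensor._accum(other, _unbroadcast(g * self.data, other.data.shape), own=True)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self.pow(-1.0)

    def pow(self, p: float):
        out_data = self.data ** p

        def bw(g):
            Tensor._accum(self, g * (p * self.data ** (p - 1.0)), own=True)

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self):
        return self.pow(0.5)

    # -- nonlinearities --------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            Tensor._accum(self, g * out_data, own=True)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            Tensor._accum(self, g / self.data, own=True)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            Tensor._accum(self, g * (1.0 - out_data * out_data), own=True)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            Tensor._accum(self, g * (out_data * (1.0 - out_data)), own=True)

        return Tensor._make(out_data, (self,), bw)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def bw(g):
            Tensor._accum(self, g * (sig * (1.0 + self.data * (1.0 - sig))), own=True)

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            Tensor._accum(self, g * mask, own=True)

        return Tensor._make(self.data * mask, (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            Tensor._accum(self, np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_detached(self, axis, keepdims=True) -> "Tensor":
        """Max along an axis with no gradient (softmax stabilisation)."""
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    def softmax(self, axis=-1):
        shifted = self - self.max_detached(axis=axis)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            Tensor._accum(self, g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            Tensor._accum(self, g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                buf[idx] += g
                Tensor._accum(self, buf, own=True)

        return Tensor._make(self.data[idx], (self,), bw)

    @staticmethod
    def concat(tensors, axis=0):
        tensors = list(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        offs = np.cumsum([0] + sizes)

        def bw(g):
            sl = [slice(None)] * g.ndim
            for t, a, b in zip(tensors, offs[:-1], offs[1:]):
                sl[axis] = slice(a, b)
                Tensor._accum(t, g[tuple(sl)])

        return Tensor._make(out_data, tuple(tensors), bw)

    def chunk(self, n, axis=1):
        step = self.data.shape[axis] // n
        out = []
        for i in range(n):
            sl = [slice(None)] * self.data.ndim
            sl[axis] = slice(i * step, (i + 1) * step)
            out.append(self[tuple(sl)])
        return out

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = Tensor._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            Tensor._accum(self, _unbroadcast(ga, self.data.shape), own=True)
            Tensor._accum(other, _unbroadcast(gb, other.data.shape), own=True)

        return Tensor._make(out_data, (self, other), bw)

    __matmul__ = matmul


class Parameter(Tensor):
    """A Tensor registered as trainable by the Module system."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
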