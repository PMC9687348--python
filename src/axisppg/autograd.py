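"""Reverse-mode automatic differentiation over numpy arrays.

The package trains a small spatio-temporal network on CPU; all learnable
computation is expressed with the :class:`Tensor` class defined here, which
records an operation graph and back-propagates cotangents through it.  Only
the operations the network and its losses need are implemented: elementwise
arithmetic with broadcasting, matrix products, shape manipulation, reductions,
a handful of nonlinearities, and trigonometric ops for the spectral loss.

Gradients are accumulated in ``float64``; graphs are discarded after
``backward`` unless the caller keeps references.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad"]


def _coerce(other, like: np.ndarray) -> "Tensor":
    if isinstance(other, Tensor):
        return other
    arr = np.asarray(other)
    if arr.dtype != like.dtype and arr.dtype.kind in "fiub" and arr.ndim == 0:
        arr = arr.astype(like.dtype)
    return Tensor(arr)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---- graph plumbing -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = _GradMode.enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        # grads may alias views of downstream buffers, so accumulation is
        # out-of-place; first contribution is stored as-is
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        break
                else:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def astype(self, dtype) -> "Tensor":
        src = self.data.dtype

        def backward(g):
            if self.requires_grad:
                self._accum(g.astype(src))

        return Tensor._make(self.data.astype(dtype), (self,), backward)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- conveniences ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = _coerce(other, self.data)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_coerce(other, self.data))

    def __rsub__(self, other):
        return _coerce(other, self.data) + (-self)

    def __mul__(self, other):
        other = _coerce(other, self.data)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _coerce(other, self.data)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _coerce(other, self.data) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # ---- shape ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def moveaxis(self, src: int, dst: int):
        axes = list(range(self.data.ndim))
        axes.insert(dst, axes.pop(src))
        return self.transpose(*axes)

    def __getitem__(self, key):
        shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                full = np.zeros(shape, dtype=g.dtype)
                np.add.at(full, key, g)
                self._accum(full)

        return Tensor._make(self.data[key], (self,), backward)

    def pad(self, pad_width):
        """Zero-pad; `pad_width` as for np.pad."""
        slices = tuple(
            slice(lo, lo + n) for (lo, _), n in zip(pad_width, self.data.shape)
        )

        def backward(g):
            if self.requires_grad:
                self._accum(g[slices])

        return Tensor._make(np.pad(self.data, pad_width), (self,), backward)

    # ---- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                mask = (self.data == out_data).astype(np.float64)
                self._accum(mask / mask.sum() * g)
                return
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            gexp = g if keepdims else np.expand_dims(g, axis)
            mask = (self.data == expanded).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            self._accum(mask * np.broadcast_to(gexp, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    # ---- elementwise nonlinearities -------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sin(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * np.cos(self.data))

        return Tensor._make(np.sin(self.data), (self,), backward)

    def cos(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g * np.sin(self.data))

        return Tensor._make(np.cos(self.data), (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def atan2(y: Tensor, x: Tensor) -> Tensor:
    """Elementwise atan2 with gradients w.r.t. both arguments."""
    y, x = as_tensor(y), as_tensor(x)
    out_data = np.arctan2(y.data, x.data)
    denom = y.data**2 + x.data**2
    denom = np.where(denom == 0.0, 1.0, denom)

    def backward(g):
        if y.requires_grad:
            y._accum(_unbroadcast(g * x.data / denom, y.data.shape))
        if x.requires_grad:
            x._accum(_unbroadcast(-g * y.data / denom, x.data.shape))

    return Tensor._make(out_data, (y, x), backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def apply_matrix_last(x: Tensor, m: np.ndarray) -> Tensor:
    """Multiply a constant matrix onto the last axis: y[..., j] = sum_i x[..., i] m[i, j]."""
    x = as_tensor(x)
    lead = x.shape[:-1]
    flat = x.reshape(int(np.prod(lead)) if lead else 1, x.shape[-1])
    out = flat @ Tensor(np.asarray(m, dtype=x.data.dtype))
    return out.reshape(*lead, m.shape[1])
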