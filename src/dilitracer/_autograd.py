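"""Compact reverse-mode automatic differentiation on NumPy arrays.

Sized for desk-scale transformer/LSTM models: a :class:`Tensor` wraps an
``ndarray``, records the operations applied to it, and :meth:`Tensor.backward`
accumulates gradients by walking the tape in reverse topological order.
Supports broadcasting for elementwise ops and batched ``matmul``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "concatenate", "stack", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype.kind != "f" else None)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument requires a scalar Tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            if t._parents == ():  # leaf
                t.grad = g if t.grad is None else t.grad + g

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):  # weak scalar: preserves dtype
            return Tensor._make(self.data + other, (self,), lambda g: [(self, g)])
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor._make(
            out_data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data * other, (self,), lambda g: [(self, g * other)])
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g / other.data, self.data.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)),
            ],
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        return Tensor._make(
            self.data**p,
            (self,),
            lambda g: [(self, g * p * self.data ** (p - 1))],
        )

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        if a.ndim > 2 and b.ndim == 2:
            # common dense-layer case: collapse leading dims into one BLAS GEMM
            lead = a.shape[:-1]
            a2 = a.reshape(-1, a.shape[-1])
            out = (a2 @ b).reshape(*lead, b.shape[1])

            def backward(g):
                g2 = g.reshape(-1, b.shape[1])
                return [(self, (g2 @ b.T).reshape(a.shape)), (other, a2.T @ g2)]

            return Tensor._make(out, (self, other), backward)
        out = a @ b

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b).reshape(a.shape)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g).reshape(b.shape)
            return [
                (self, _unbroadcast(ga, a.shape)),
                (other, _unbroadcast(gb, b.shape)),
            ]

        return Tensor._make(out, (self, other), backward)

    __matmul__ = matmul

    def transpose(self, *axes):
        axes = axes or None
        out = np.transpose(self.data, axes)
        if axes is None:
            inv = None
        else:
            inv = np.argsort(axes)
        return Tensor._make(
            out, (self,), lambda g: [(self, np.transpose(g, inv))]
        )

    def swapaxes(self, a, b):
        return Tensor._make(
            np.swapaxes(self.data, a, b),
            (self,),
            lambda g: [(self, np.swapaxes(g, a, b))],
        )

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: [(self, g.reshape(old))]
        )

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return [(self, full)]

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.data.shape).copy())]
            g2 = g if keepdims else np.expand_dims(g, axis)
            return [(self, np.broadcast_to(g2, self.data.shape).copy())]

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: [(self, g * out)])

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), lambda g: [(self, g / self.data)]
        )

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: [(self, g * 0.5 / out)])

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: [(self, g * (1.0 - out**2))])

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: [(self, g * out * (1.0 - out))])

    def gelu(self):
        # sigmoid-approximation GELU: x * sigmoid(1.702 x)
        x = self.data
        s = 1.0 / (1.0 + np.exp(-1.702 * x))
        return Tensor._make(
            x * s,
            (self,),
            lambda g: [(self, g * (s + 1.702 * x * s * (1.0 - s)))],
        )

    def softmax(self, axis=-1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return [(self, out * (g - dot))]

        return Tensor._make(out, (self,), backward)

    def log_softmax(self, axis=-1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        s = np.log(np.exp(x - m).sum(axis=axis, keepdims=True)) + m
        out = x - s
        soft = np.exp(out)

        def backward(g):
            return [(self, g - soft * g.sum(axis=axis, keepdims=True))]

        return Tensor._make(out, (self,), backward)

    def layer_norm(self, axis=-1, eps: float = 1e-6):
        """Normalize to zero mean / unit variance along `axis` (no affine)."""
        x = self.data
        mu = x.mean(axis=axis, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=axis, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out = xc * inv
        n = x.shape[axis]

        def backward(g):
            gm = g.mean(axis=axis, keepdims=True)
            gxn = (g * out).mean(axis=axis, keepdims=True)
            return [(self, inv * (g - gm - out * gxn))]

        return Tensor._make(out, (self,), backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    __slots__ = ()

    def __init__(self, data):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        super().__init__(arr)
        self.requires_grad = True


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return Tensor._make(out, tensors, backward)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        return [(t, np.squeeze(p, axis=axis)) for t, p in zip(tensors, parts)]

    return Tensor._make(out, tensors, backward)
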