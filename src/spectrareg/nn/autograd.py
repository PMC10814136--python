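"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the deep regression models (1-D CNN,
LSTM, Transformer encoder) and behind Grad-CAM, which needs gradients of
the scalar output with respect to an intermediate convolutional feature
map.  The engine is deliberately small: a ``Tensor`` wraps an ndarray,
records its parents and a backward closure, and ``backward()`` walks the
graph in reverse topological order accumulating ``.grad`` on every node
that requires gradients.  All gradients are retained (not just leaves),
which is what saliency extraction relies on.

Arrays default to float32 for speed; float64 inputs are preserved so the
same primitives can be checked against high-precision oracles.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ParameterError

__all__ = ["Tensor", "as_tensor", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (cheap inference passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _coerce(data):
    # python scalars become float32 so they never promote a float32 graph
    # to float64 (float64 arrays still win the usual numpy promotion)
    if isinstance(data, (int, float)):
        return np.float32(data)
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over broadcast dimensions so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _coerce(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls.__new__(cls)
        out.data = data
        out.grad = None
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        o = as_tensor(other)
        data = self.data + o.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.data.shape))

        return Tensor._from_op(data, (self, o), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        data = self.data * o.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._from_op(data, (self, o), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        data = self.data / o.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(-g * self.data / (o.data * o.data), o.data.shape))

        return Tensor._from_op(data, (self, o), backward)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise ParameterError("only scalar exponents are supported")
        data = self.data ** exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(data, (self,), backward)

    def __matmul__(self, other):
        o = as_tensor(other)
        data = self.data @ o.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.data.shape))

        return Tensor._from_op(data, (self, o), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0
        data = np.where(mask, self.data, 0)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._from_op(data, (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1 - data * data))

        return Tensor._from_op(data, (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * data * (1 - data))

        return Tensor._from_op(data, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * data)

        return Tensor._from_op(data, (self,), backward)

    def sqrt(self):
        data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / data)

        return Tensor._from_op(data, (self,), backward)

    # -- reductions and shape ops ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, shape))

        return Tensor._from_op(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._from_op(data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        data = np.ascontiguousarray(self.data.transpose(axes))

        def backward(g):
            self._accumulate(g.transpose(tuple(inverse)))

        return Tensor._from_op(data, (self,), backward)

    def __getitem__(self, idx):
        data = self.data[idx]
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=self.data.dtype)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._from_op(data, (self,), backward)

    # -- fused primitives (speed / stability) ----------------------------------

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis``."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * data).sum(axis=axis, keepdims=True)
            self._accumulate(data * (g - dot))

        return Tensor._from_op(data, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Layer normalization over the last axis with affine parameters."""
        x = self.data
        n = x.shape[-1]
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        data = gamma.data * xhat + beta.data

        def backward(g):
            if gamma.requires_grad:
                axes = tuple(range(g.ndim - 1))
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                axes = tuple(range(g.ndim - 1))
                beta._accumulate(g.sum(axis=axes))
            if self.requires_grad:
                gx = g * gamma.data
                mean_gx = gx.mean(axis=-1, keepdims=True)
                mean_gxx = (gx * xhat).mean(axis=-1, keepdims=True)
                self._accumulate(inv * (gx - mean_gx - xhat * mean_gxx))

        return Tensor._from_op(data, (self, gamma, beta), backward)

    def conv1d(self, weight: "Tensor", bias: "Tensor", padding: int):
        """1-D cross-correlation, stride 1.

        ``self``: (N, C_in, L); ``weight``: (C_out, C_in, K); output (N, C_out, L_out)
        with L_out = L + 2*padding - K + 1.
        """
        x = self.data
        w = weight.data
        n, c_in, length = x.shape
        c_out, _, k = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding))) if padding else x
        l_out = xp.shape[2] - k + 1
        # im2col: (N, L_out, C_in * K)
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N, C_in, L_out, K)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n * l_out, c_in * k)
        w_mat = w.reshape(c_out, c_in * k)
        out = cols @ w_mat.T
        out = out.reshape(n, l_out, c_out).transpose(0, 2, 1)
        out = np.ascontiguousarray(out) + bias.data[None, :, None]

        def backward(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(n * l_out, c_out)
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2)))
            if weight.requires_grad:
                weight._accumulate((g2.T @ cols).reshape(c_out, c_in, k))
            if self.requires_grad:
                gcols = (g2 @ w_mat).reshape(n, l_out, c_in, k).transpose(0, 2, 1, 3)
                gxp = np.zeros_like(xp)
                for j in range(k):
                    gxp[:, :, j:j + l_out] += gcols[:, :, :, j]
                if padding:
                    gxp = gxp[:, :, padding:-padding]
                self._accumulate(gxp)

        return Tensor._from_op(out, (self, weight, bias), backward)

    # -- backward pass ---------------------------------------------------------

    def backward(self, grad=None):
        if not self.requires_grad:
            raise ParameterError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ParameterError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))

        order: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)
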