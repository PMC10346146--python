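"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine in the micrograd style, but array-valued: each
:class:`Tensor` wraps an ``ndarray`` and records a closure that scatters the
upstream gradient to its parents.  Only the operations the segmentation
network needs are implemented (elementwise arithmetic, matmul, reductions,
shape ops, slicing/concatenation, 2-D convolution and bilinear resizing).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

__all__ = ["Tensor", "cat", "stack", "conv2d", "resize_bilinear", "gelu_np"]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
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
    # keep NumPy from hijacking mixed Tensor/ndarray operators
    __array_priority__ = 1000
    __array_ufunc__ = None

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ meta
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

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- backprop
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ----------------------------------------------------------- op helpers
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _acc(self, g: np.ndarray) -> None:
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._acc(_unbroadcast(g, self.data.shape))
            other._acc(_unbroadcast(g, other.data.shape))

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._acc(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._acc(_unbroadcast(g * other.data, self.data.shape))
            other._acc(_unbroadcast(g * self.data, other.data.shape))

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            self._acc(g * exponent * self.data ** (exponent - 1))

        return self._node(self.data ** exponent, (self,), backward)

    def __truediv__(self, other):
        if np.isscalar(other):
            return self * (1.0 / other)
        return self * (self._lift(other) ** -1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * (self ** -1.0)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            self._acc(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            other._acc(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        return self._node(out_data, (self, other), backward)

    def __rmatmul__(self, other):
        return self._lift(other) @ self

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._acc(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._acc(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._acc(g * 0.5 / out_data)

        return self._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._acc(g * mask)

        return self._node(self.data * mask, (self,), backward)

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + special.erf(x / _SQRT2))

        def backward(g):
            pdf = np.exp(-0.5 * x * x) * _INV_SQRT_2PI
            self._acc(g * (phi + x * pdf))

        return self._node(x * phi, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._acc(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape).copy())

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def backward(g):
            self._acc(g.reshape(src))

        return self._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._acc(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._acc(full)

        return self._node(self.data[idx], (self,), backward)


# ---------------------------------------------------------------- functions
def cat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._acc(g[tuple(sl)])

    return Tensor._node(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._acc(np.take(g, i, axis=axis))

    return Tensor._node(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, weight: Tensor, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    x = Tensor._lift(x)
    weight = Tensor._lift(weight)
    xd, wd = x.data, weight.data
    n, cin, h, w = xd.shape
    cout, cin_w, kh, kw = wd.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = xd
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, ho, wo, cin, kh, kw),
        strides=(s0, s2 * stride, s3 * stride, s1, s2, s3),
        writeable=False,
    ).reshape(n * ho * wo, cin * kh * kw)
    wmat = wd.reshape(cout, -1)
    out = cols @ wmat.T
    parents = [x, weight]
    if bias is not None:
        bias = Tensor._lift(bias)
        out = out + bias.data
        parents.append(bias)
    out_data = np.ascontiguousarray(out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2))

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        weight._acc((gmat.T @ cols).reshape(wd.shape))
        if bias is not None:
            bias._acc(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, cin, kh, kw)
            dxp = np.zeros((n, cin, hp, wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._acc(dxp)

    return Tensor._node(out_data, tuple(parents), backward)


def batch_norm_2d(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
                  var: np.ndarray, eps: float, batch_stats: bool) -> Tensor:
    """Channelwise normalization of an NCHW tensor as one fused primitive.

    ``mean``/``var`` are plain arrays of shape (C,).  With ``batch_stats``
    they are the statistics of ``x`` itself and the backward pass carries
    the full batch-norm gradient; otherwise they are treated as constants
    (running statistics in eval mode)."""
    x = Tensor._lift(x)
    gamma = Tensor._lift(gamma)
    beta = Tensor._lift(beta)
    c = x.data.shape[1]
    shape = (1, c, 1, 1)
    inv_std = (1.0 / np.sqrt(var + eps)).reshape(shape).astype(x.data.dtype)
    xhat = (x.data - mean.reshape(shape)) * inv_std
    out_data = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        gamma._acc((g * xhat).sum(axis=(0, 2, 3)))
        beta._acc(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gx = g * gamma.data.reshape(shape)
        if batch_stats:
            mean_gx = gx.mean(axis=(0, 2, 3), keepdims=True)
            mean_gx_xhat = (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x._acc(inv_std * (gx - mean_gx - xhat * mean_gx_xhat))
        else:
            x._acc(inv_std * gx)

    return Tensor._node(out_data, (x, gamma, beta), backward)


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D linear-interpolation operator (align_corners=False)."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    m = np.zeros((n_out, n_in), dtype=dtype)
    m[np.arange(n_out), i0] += 1.0 - t
    m[np.arange(n_out), i1] += t
    return m


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear spatial resizing of an NCHW tensor (a fixed linear map)."""
    x = Tensor._lift(x)
    n, c, h, w = x.data.shape
    mr = _interp_matrix(h, out_h, x.data.dtype)
    mc = _interp_matrix(w, out_w, x.data.dtype)
    out_data = mr @ x.data @ mc.T

    def backward(g):
        x._acc(mr.T @ g @ mc)

    return Tensor._node(out_data, (x,), backward)


def gelu_np(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) GELU on a plain array."""
    return 0.5 * x * (1.0 + special.erf(x / _SQRT2))
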