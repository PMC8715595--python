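"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the primitives the displacement-prediction
network and its hybrid loss need: elementwise arithmetic, N-D stride-1
"same" convolution with dilation, 2x max pooling / nearest upsampling,
channel concatenation, dropout, an edge-clamped box-sum filter (for the
windowed-NCC loss), and a differentiable backward-warp sampler. Each
primitive carries a hand-derived adjoint; the test suite checks every one
against central finite differences.

Tensors wrap numpy arrays of whatever float dtype they are given (the
network uses float32 for speed; gradient checks use float64). Graphs are
rebuilt on every forward pass, micrograd-style; ``Tensor.backward`` runs a
topological sweep.
"""
from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "convnd",
    "maxpool2",
    "upsample2",
    "leaky_relu",
    "dropout",
    "boxsum",
    "warp_sample",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph machinery ---------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = np.zeros_like(t.data, dtype=t.data.dtype)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if self.requires_grad:
            self.grad += _unbroadcast(np.asarray(grad), self.data.shape)

    # -- elementwise ops ---------------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, (self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, (self, other))
        out._backward = lambda g: (
            self._accum(g * other.data),
            other._accum(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, (self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / other.data**2),
        )
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def square(self):
        out = Tensor(self.data**2, (self,))
        out._backward = lambda g: self._accum(2.0 * g * self.data)
        return out

    def sqrt(self):
        root = np.sqrt(self.data)
        out = Tensor(root, (self,))
        out._backward = lambda g: self._accum(0.5 * g / root)
        return out

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), (self,))

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape))

        out._backward = back
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)


# -- structural / neural-net primitives -------------------------------------


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the leading (channel) axis."""
    na = a.data.shape[0]
    out = Tensor(np.concatenate([a.data, b.data], axis=0), (a, b))
    out._backward = lambda g: (a._accum(g[:na]), b._accum(g[na:]))
    return out


def _conv_raw(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Stride-1 zero-padded 'same' cross-correlation.

    ``x``: (Cin, *S); ``w``: (Cout, Cin, *K) with odd cubic kernel.
    """
    d = x.ndim - 1
    k = w.shape[2]
    pad = dilation * (k // 2)
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * d)
    win = (dilation * (k - 1) + 1,) * d
    v = sliding_window_view(xp, win, axis=tuple(range(1, 1 + d)))
    if dilation > 1:
        sl = (slice(None),) * (1 + d) + (slice(None, None, dilation),) * d
        v = v[sl]
    # contract Cin and the kernel axes
    axes_w = [1] + list(range(2, 2 + d))
    axes_v = [0] + list(range(1 + d, 1 + 2 * d))
    return np.tensordot(w, v, axes=(axes_w, axes_v))


def convnd(x: Tensor, w: Tensor, b: Optional[Tensor] = None, dilation: int = 1) -> Tensor:
    """N-D convolution, stride 1, zero 'same' padding, square odd kernel."""
    d = x.data.ndim - 1
    k = w.data.shape[2]
    if k % 2 != 1:
        raise ValueError("kernel size must be odd")
    y = _conv_raw(x.data, w.data, dilation)
    if b is not None:
        y = y + b.data.reshape((-1,) + (1,) * d)
        out = Tensor(y, (x, w, b))
    else:
        out = Tensor(y, (x, w))

    def back(g):
        g = np.ascontiguousarray(g)
        if x.requires_grad:
            # adjoint of 'same' stride-1 conv: conv with channel-transposed,
            # spatially flipped kernel at the same dilation
            flip = (slice(None), slice(None)) + (slice(None, None, -1),) * d
            wt = np.ascontiguousarray(w.data.transpose((1, 0) + tuple(range(2, 2 + d)))[flip])
            x._accum(_conv_raw(g, wt, dilation))
        if w.requires_grad:
            pad = dilation * (k // 2)
            xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * d)
            win = (dilation * (k - 1) + 1,) * d
            v = sliding_window_view(xp, win, axis=tuple(range(1, 1 + d)))
            if dilation > 1:
                sl = (slice(None),) * (1 + d) + (slice(None, None, dilation),) * d
                v = v[sl]
            spatial = list(range(1, 1 + d))
            w._accum(np.tensordot(g, v, axes=(spatial, spatial)))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=tuple(range(1, 1 + d))))

    out._backward = back
    return out


def _blocked(x: np.ndarray):
    """Reshape (C, *S) -> (C, *S/2, 2**d) exposing 2x2(x2) blocks."""
    d = x.ndim - 1
    shape = (x.shape[0],)
    for s in x.shape[1:]:
        shape += (s // 2, 2)
    v = x.reshape(shape)
    # move the block axes to the end
    perm = (0,) + tuple(1 + 2 * i for i in range(d)) + tuple(2 + 2 * i for i in range(d))
    v = v.transpose(perm)
    return v.reshape(v.shape[: 1 + d] + (2**d,))


def _unblock(v: np.ndarray, out_shape: tuple):
    d = len(out_shape) - 1
    half = out_shape[1:]
    v = v.reshape((out_shape[0],) + tuple(s // 2 for s in half) + (2,) * d)
    inv = [0]
    for i in range(d):
        inv += [1 + i, 1 + d + i]
    return v.transpose(inv).reshape(out_shape)


def maxpool2(x: Tensor) -> Tensor:
    """Max pooling with window and stride 2 along every spatial axis."""
    if any(s % 2 for s in x.data.shape[1:]):
        raise ValueError(f"maxpool2 needs even spatial axes, got {x.data.shape[1:]}")
    v = _blocked(x.data)
    idx = v.argmax(axis=-1)
    out = Tensor(np.take_along_axis(v, idx[..., None], axis=-1)[..., 0], (x,))

    def back(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        x._accum(_unblock(gv, x.data.shape))

    out._backward = back
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along every spatial axis."""
    y = x.data
    for ax in range(1, y.ndim):
        y = np.repeat(y, 2, axis=ax)
    out = Tensor(y, (x,))

    def back(g):
        x._accum(_blocked(g).sum(axis=-1))

    out._backward = back
    return out


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, alpha * x.data), (x,))
    out._backward = lambda g: x._accum(np.where(mask, g, alpha * g))
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p == 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = Tensor(x.data * keep, (x,))
    out._backward = lambda g: x._accum(g * keep)
    return out


def instance_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes (batch-free).

    ``x``: (C, *S); ``g``/``b``: per-channel scale and shift of shape (C,).
    """
    d = x.data.ndim - 1
    axes = tuple(range(1, 1 + d))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    s = np.sqrt(var + eps)
    y = (x.data - mu) / s
    shape = (-1,) + (1,) * d
    out = Tensor(y * g.data.reshape(shape) + b.data.reshape(shape), (x, g, b))

    def back(grad):
        if g.requires_grad:
            g._accum((grad * y).sum(axis=axes))
        if b.requires_grad:
            b._accum(grad.sum(axis=axes))
        if x.requires_grad:
            dy = grad * g.data.reshape(shape)
            m1 = dy.mean(axis=axes, keepdims=True)
            m2 = (dy * y).mean(axis=axes, keepdims=True)
            x._accum((dy - m1 - y * m2) / s)

    out._backward = back
    return out


# -- edge-clamped box sum (separable) ----------------------------------------


def _movsum_valid(a: np.ndarray, axis: int, w: int) -> np.ndarray:
    c = np.cumsum(a, axis=axis)
    n = a.shape[axis] - w + 1
    head = np.take(c, np.arange(w - 1, w - 1 + n), axis=axis)
    tail = np.take(c, np.arange(0, n - 1), axis=axis)
    pad = [(0, 0)] * a.ndim
    pad[axis] = (1, 0)
    return head - np.pad(tail, pad)


def _boxsum_axis(a: np.ndarray, axis: int, r: int) -> np.ndarray:
    pad = [(0, 0)] * a.ndim
    pad[axis] = (r, r)
    return _movsum_valid(np.pad(a, pad, mode="edge"), axis, 2 * r + 1)


def _boxsum_axis_adjoint(g: np.ndarray, axis: int, r: int) -> np.ndarray:
    pad = [(0, 0)] * g.ndim
    pad[axis] = (2 * r, 2 * r)
    z = _movsum_valid(np.pad(g, pad), axis, 2 * r + 1)  # length n + 2r
    n = g.shape[axis]
    mid = np.take(z, np.arange(r, r + n), axis=axis)
    # fold the edge-replication pads back onto the border elements
    first = np.take(z, np.arange(0, r), axis=axis).sum(axis=axis, keepdims=True)
    last = np.take(z, np.arange(n + r, n + 2 * r), axis=axis).sum(axis=axis, keepdims=True)
    idx0 = np.take(mid, [0], axis=axis) + first
    idxn = np.take(mid, [n - 1], axis=axis) + last
    body = np.take(mid, np.arange(1, n - 1), axis=axis)
    return np.concatenate([idx0, body, idxn], axis=axis)


def boxsum_raw(a: np.ndarray, r: int) -> np.ndarray:
    for ax in range(a.ndim):
        a = _boxsum_axis(a, ax, r)
    return a


def boxsum(x: Tensor, r: int) -> Tensor:
    """Sum over the (2r+1)^d window around every voxel, borders edge-clamped."""
    out = Tensor(boxsum_raw(x.data, r), (x,))

    def back(g):
        for ax in range(g.ndim):
            g = _boxsum_axis_adjoint(g, ax, r)
        x._accum(g)

    out._backward = back
    return out


# -- differentiable backward warp --------------------------------------------


def warp_sample(image: np.ndarray, u: Tensor) -> Tensor:
    """Sample ``image`` at ``grid + u`` with multilinear interpolation.

    ``image`` is a constant (*S,) array; ``u`` has shape (*S, d) in voxel
    units. Out-of-grid coordinates are border-clamped (matching
    ``scipy.ndimage.map_coordinates(order=1, mode='nearest')``). The
    gradient is taken with respect to ``u`` only.
    """
    d = image.ndim
    if u.data.shape != image.shape + (d,):
        raise ValueError("field shape must be image shape + (d,)")
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=u.data.dtype) for n in image.shape], indexing="ij"),
        axis=-1,
    )
    coords = grid + u.data
    lo = np.floor(coords)
    frac = coords - lo
    lo = lo.astype(np.int64)
    out_val = np.zeros(image.shape, dtype=image.dtype)
    grads = np.zeros_like(u.data)
    corner_vals = []
    for corner in itertools.product((0, 1), repeat=d):
        idx = tuple(
            np.clip(lo[..., ax] + corner[ax], 0, image.shape[ax] - 1) for ax in range(d)
        )
        corner_vals.append((corner, image[idx]))
        wgt = np.ones(image.shape, dtype=u.data.dtype)
        for ax in range(d):
            wgt = wgt * (frac[..., ax] if corner[ax] else 1.0 - frac[..., ax])
        out_val = out_val + wgt * corner_vals[-1][1]
    # analytic d(out)/d(u_k)
    for k in range(d):
        acc = np.zeros(image.shape, dtype=u.data.dtype)
        for corner, val in corner_vals:
            wgt = np.ones(image.shape, dtype=u.data.dtype)
            for ax in range(d):
                if ax == k:
                    continue
                wgt = wgt * (frac[..., ax] if corner[ax] else 1.0 - frac[..., ax])
            acc += (1.0 if corner[k] else -1.0) * wgt * val
        grads[..., k] = acc
    out = Tensor(out_val, (u,))
    out._backward = lambda g: u._accum(g[..., None] * grads)
    return out


# -- optimizer ----------------------------------------------------------------


class Adam:
    """Adam with the usual default moments (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
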