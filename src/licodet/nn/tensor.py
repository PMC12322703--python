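"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` walks the tape in reverse topological order.
Convolutions are lowered to GEMM via im2col, so the heavy lifting runs in
BLAS.  A process-global profiler (:func:`flop_profiler`) records 2*M*N*K for
every GEMM actually executed — the runtime cross-check for the analytic FLOP
accountant in :mod:`licodet.flops`.
"""
from __future__ import annotations

import contextlib
import math
from typing import Iterable

import numpy as np

_PROFILE: list | None = None


@contextlib.contextmanager
def flop_profiler():
    """Count 2 FLOPs per multiply-accumulate over every GEMM executed inside."""
    global _PROFILE
    prev, _PROFILE = _PROFILE, []
    try:
        yield _PROFILE
    finally:
        _PROFILE = prev


def _record_gemm(flops: int) -> None:
    if _PROFILE is not None:
        _PROFILE.append(flops)


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "retains_grad")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self.retains_grad = False

    # -- housekeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # interior node: its grad and tape entry are no longer needed
                if not node.retains_grad:
                    node.grad = None
                node._backward = None
                node._prev = ()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other, dtype=np.float32))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.reciprocal()

    def reciprocal(self):
        out = Tensor(1.0 / self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g / (self.data * self.data))
        out._backward = bwd
        return out

    def pow(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.matmul(self.data, other.data)
        m, k = self.data.shape[-2], self.data.shape[-1]
        n = other.data.shape[-1]
        batch = int(np.prod(out_data.shape[:-2], dtype=np.int64)) if out_data.ndim > 2 else 1
        _record_gemm(2 * batch * m * n * k)
        out = Tensor(out_data, self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)),
                                         self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g),
                                          other.data.shape))
        out._backward = bwd
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bwd
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))
        out._backward = bwd
        return out

    def softplus(self):
        x = self.data
        y = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-np.clip(x, -60, 60))))
        out._backward = bwd
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -60, 60))
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def arctan(self):
        out = Tensor(np.arctan(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data * self.data))
        out._backward = bwd
        return out

    def clamp_min(self, lo: float):
        out = Tensor(np.maximum(self.data, lo), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data >= lo))
        out._backward = bwd
        return out

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        idx = np.argmax(self.data, axis=axis)
        y = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            y = np.squeeze(y, axis=axis)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(gx)
        out._backward = bwd
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, key, g)
                self._accum(gx)
        out._backward = bwd
        return out

    def broadcast_to(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape).copy(), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
        out._backward = bwd
        return out


# -- free functions --------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)
    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            gx = y * (g - (g * y).sum(axis=axis, keepdims=True))
            x._accum(gx)
    out._backward = bwd
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    mask = a.data <= b.data
    out = Tensor(np.where(mask, a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))
    out._backward = bwd
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    mask = a.data >= b.data
    out = Tensor(np.where(mask, a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))
    out._backward = bwd
    return out


# -- spatial ops ------------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(x: Tensor, w: Tensor, stride=1, padding=0, dilation=1, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution via im2col + batched GEMM.

    x: (N, C, H, W); w: (Cout, C//groups, kh, kw).
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    N, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    g = groups
    assert C == Cg * g and Cout % g == 0
    ekh, ekw = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    Ho = (H + 2 * ph - ekh) // sh + 1
    Wo = (W + 2 * pw - ekw) // sw + 1

    def im2col():
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
        win = np.lib.stride_tricks.sliding_window_view(xp, (ekh, ekw), axis=(2, 3))
        win = win[:, :, ::sh, ::sw, ::dh, ::dw]      # (N,C,Ho,Wo,kh,kw)
        cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
        return cols.reshape(N, g, Cg * kh * kw, Ho * Wo)

    cols = im2col()
    wr = w.data.reshape(g, Cout // g, Cg * kh * kw)
    out_data = np.matmul(wr[None], cols)             # (N,g,Cout/g,Ho*Wo)
    _record_gemm(2 * N * g * (Cout // g) * (Cg * kh * kw) * (Ho * Wo))
    del cols                                         # rebuilt on demand in backward
    out_data = out_data.reshape(N, Cout, Ho, Wo)
    out = Tensor(out_data, x.requires_grad or w.requires_grad, (x, w))

    def bwd(gout):
        go = gout.reshape(N, g, Cout // g, Ho * Wo)
        if w.requires_grad:
            cols = im2col()
            gw = np.matmul(go, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            del cols
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wr.transpose(0, 2, 1)[None], go)    # (N,g,CgK,HoWo)
            g6 = gcols.reshape(N, C, kh, kw, Ho, Wo)
            gx = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=np.float32)
            for i in range(kh):
                ii = i * dh
                for j in range(kw):
                    jj = j * dw
                    gx[:, :, ii:ii + sh * Ho:sh, jj:jj + sw * Wo:sw] += g6[:, :, i, j]
            if ph or pw:
                gx = gx[:, :, ph:ph + H, pw:pw + W]
            x._accum(gx)
    out._backward = bwd
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    N, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    neg = np.float32(-np.inf)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=neg) if p else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(N, C, Ho, Wo, k * k)
    idx = np.argmax(flat, axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xp)
        oh, ow = np.meshgrid(np.arange(Ho), np.arange(Wo), indexing="ij")
        hsrc = oh[None, None] * s + idx // k
        wsrc = ow[None, None] * s + idx % k
        nn, cc = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
        np.add.at(gx, (nn[..., None, None], cc[..., None, None], hsrc, wsrc), g)
        x._accum(gx[:, :, p:p + H, p:p + W] if p else gx)
    out._backward = bwd
    return out


def avg_pool2d(x: Tensor, pool: int) -> Tensor:
    """Count-corrected average pooling with stride == kernel == ``pool``.

    Inputs whose sides do not divide ``pool`` are zero-padded on the
    bottom/right and each cell is divided by the number of real pixels in it.
    """
    N, C, H, W = x.data.shape
    p = pool
    Hb, Wb = -(-H // p), -(-W // p)
    pad_h, pad_w = Hb * p - H, Wb * p - W
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w))) if (pad_h or pad_w) else x.data
    blocks = xp.reshape(N, C, Hb, p, Wb, p)
    cnt_h = np.minimum(np.arange(1, Hb + 1) * p, H) - np.arange(Hb) * p
    cnt_w = np.minimum(np.arange(1, Wb + 1) * p, W) - np.arange(Wb) * p
    counts = (cnt_h[:, None] * cnt_w[None, :]).astype(np.float32)
    y = blocks.sum(axis=(3, 5)) / counts
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gb = (g / counts)[:, :, :, None, :, None]
        gx = np.broadcast_to(gb, (N, C, Hb, p, Wb, p)).reshape(N, C, Hb * p, Wb * p)
        x._accum(gx[:, :, :H, :W])
    out._backward = bwd
    return out


def _adaptive_bounds(n_in: int, n_out: int):
    starts = [(i * n_in) // n_out for i in range(n_out)]
    ends = [-((-(i + 1) * n_in) // n_out) for i in range(n_out)]
    return starts, ends


def _adaptive_pool_axis(x: Tensor, out_size: int, axis: int) -> Tensor:
    n_in = x.data.shape[axis]
    if n_in == out_size:
        return x
    starts, ends = _adaptive_bounds(n_in, out_size)
    idx = [slice(None)] * x.data.ndim
    pieces = []
    for s, e in zip(starts, ends):
        idx[axis] = slice(s, e)
        pieces.append(x.data[tuple(idx)].mean(axis=axis, keepdims=True))
    out = Tensor(np.concatenate(pieces, axis=axis), x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        gi = [slice(None)] * x.data.ndim
        oi = [slice(None)] * x.data.ndim
        for i, (s, e) in enumerate(zip(starts, ends)):
            gi[axis] = slice(s, e)
            oi[axis] = slice(i, i + 1)
            gx[tuple(gi)] += g[tuple(oi)] / (e - s)
        x._accum(gx)
    out._backward = bwd
    return out


def adaptive_avg_pool2d(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Average pooling to an exact output grid with near-uniform windows.

    Window (i, j) covers rows [floor(iH/oh), ceil((i+1)H/oh)); separable,
    so it is applied one axis at a time.
    """
    return _adaptive_pool_axis(_adaptive_pool_axis(x, out_h, 2), out_w, 3)


def _interp_weights(n_in: int, n_out: int):
    # align_corners=False convention
    pos = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    i0 = np.floor(pos).astype(np.int64)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (pos - i0).astype(np.float32)
    return i0, i1, w1


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    N, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    i0, i1, wh = _interp_weights(H, out_h)
    j0, j1, ww = _interp_weights(W, out_w)
    rows = x.data[:, :, i0, :] * (1 - wh)[None, None, :, None] \
        + x.data[:, :, i1, :] * wh[None, None, :, None]
    y = rows[:, :, :, j0] * (1 - ww)[None, None, None, :] \
        + rows[:, :, :, j1] * ww[None, None, None, :]
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        grows = np.zeros((N, C, out_h, W), dtype=np.float32)
        np.add.at(grows, (slice(None), slice(None), slice(None), j0), g * (1 - ww)[None, None, None, :])
        np.add.at(grows, (slice(None), slice(None), slice(None), j1), g * ww[None, None, None, :])
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), i0), grows * (1 - wh)[None, None, :, None])
        np.add.at(gx, (slice(None), slice(None), i1), grows * wh[None, None, :, None])
        x._accum(gx)
    out._backward = bwd
    return out
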