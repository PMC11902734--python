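"""Reverse-mode automatic differentiation on numpy arrays.

The network blocks in this package are pure array transforms; this module
supplies the tape they record onto and the handful of differentiable
operations they need (dense and depthwise 2-D convolution, max pooling,
batch normalisation, nearest-neighbour upsampling, the usual elementwise
and reduction ops).  Dense convolutions are lowered to a single BLAS
matmul through an im2col buffer that is kept alive for the backward pass;
depthwise convolutions use a shift-and-accumulate scheme instead, which
avoids materialising per-channel GEMMs.

Layout convention: feature maps are (batch, channels, height, width),
float32 by default.
"""

from __future__ import annotations

import contextlib
import ctypes
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

DTYPE = np.float32

# Large per-step allocations (im2col buffers, gradients) otherwise go
# through mmap and pay page-zeroing on every training step; keep them on
# the heap free list instead.  No-op where glibc is unavailable.
try:  # pragma: no cover - platform dependent
    _libc = ctypes.CDLL("libc.so.6")
    _libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
    _libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
except OSError:  # pragma: no cover
    pass

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (inference fast path)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    # make numpy defer mixed ndarray/Tensor arithmetic to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=DTYPE)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward: Callable | None = backward if self.requires_grad else None
        self._parents: tuple = tuple(parents) if self.requires_grad else ()
        self.name = name

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        """Add ``g`` to this tensor's gradient.

        ``own=True`` promises that ``g`` is a freshly allocated array the
        caller will not reuse, so it can be stored without a defensive
        copy; passthrough gradients (views, shared buffers) must leave
        ``own`` False.
        """
        if self.grad is None:
            if own and g.dtype == self.data.dtype and g.flags.writeable:
                self.grad = g
            else:
                self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient on non-scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def astensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=DTYPE))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents, backward=backward if req else None)


# -- elementwise arithmetic ------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            ga = _unbroadcast(g, a.data.shape)
            a._accumulate(ga, own=ga is not g)
        if b.requires_grad:
            gb = _unbroadcast(g, b.data.shape)
            b._accumulate(gb, own=gb is not g)

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape), own=True)
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape), own=True)

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = astensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0), own=True)

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = astensor(a)
    y = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * y, own=True)

    return _make(y, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data, own=True)

    return _make(np.log(a.data), (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    y = expit(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * y * (1.0 - y), own=True)

    return _make(y, (a,), backward)


def silu(a) -> Tensor:
    a = astensor(a)
    s = expit(a.data)
    y = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (s * (1.0 + a.data * (1.0 - s))), own=True)

    return _make(y, (a,), backward)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask, own=True)

    return _make(a.data * mask, (a,), backward)


def tanh(a) -> Tensor:
    a = astensor(a)
    y = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - y * y), own=True)

    return _make(y, (a,), backward)


def arctan(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / (1.0 + a.data * a.data), own=True)

    return _make(np.arctan(a.data), (a,), backward)


def maximum(a, b) -> Tensor:
    """Elementwise max; on ties the gradient goes to ``a``."""
    a, b = astensor(a), astensor(b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.data.shape), own=True)
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~take_a), b.data.shape), own=True)

    return _make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    take_a = a.data <= b.data
    out_data = np.where(take_a, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.data.shape), own=True)
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~take_a), b.data.shape), own=True)

    return _make(out_data, (a, b), backward)


# -- reductions and shaping ------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    orig = a.data.shape

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def _is_basic_index(idx) -> bool:
    parts = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(p, (slice, int)) or p is Ellipsis for p in parts)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out_data = a.data[idx]
    basic = _is_basic_index(idx)

    def backward(g):
        if a.requires_grad:
            da = np.zeros_like(a.data)
            if basic:
                da[idx] += g
            else:  # fancy indexing may repeat positions
                np.add.at(da, idx, g)
            a._accumulate(da, own=True)

    return _make(np.ascontiguousarray(out_data), (a,), backward)


def concat(parts: Sequence[Tensor], axis: int = 1) -> Tensor:
    parts = [astensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(parts), backward)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape), own=True)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape), own=True)

    return _make(out_data, (a, b), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = astensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            a._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)), own=True)

    return _make(y, (a,), backward)


# -- spatial ops -----------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(xdata: np.ndarray, kh: int, kw: int, s: int, p: int) -> tuple:
    """Column buffer (C*kh*kw, B*Ho*Wo) of a padded NCHW array."""
    B, C, H, W = xdata.shape
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    if kh == 1 and kw == 1 and s == 1 and p == 0:
        return xdata.transpose(1, 0, 2, 3).reshape(C, B * Ho * Wo), Ho, Wo
    xp = _pad_hw(xdata, p)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # (B, C, Ho, Wo, kh, kw)
    cols = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)).reshape(
        C * kh * kw, B * Ho * Wo)
    return cols, Ho, Wo


def _conv_data(xdata: np.ndarray, wdata: np.ndarray, s: int, p: int) -> tuple:
    """Raw convolution forward; returns (out NCHW, cols buffer)."""
    B = xdata.shape[0]
    Co, C, kh, kw = wdata.shape
    cols, Ho, Wo = _im2col(xdata, kh, kw, s, p)
    out2 = wdata.reshape(Co, C * kh * kw) @ cols
    out = np.ascontiguousarray(out2.reshape(Co, B, Ho, Wo).transpose(1, 0, 2, 3))
    return out, cols


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D convolution (cross-correlation), NCHW / (Co, Ci, kh, kw)."""
    x, w = astensor(x), astensor(w)
    B, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
    s, p = stride, padding
    out_data, cols = _conv_data(x.data, w.data, s, p)
    Ho, Wo = out_data.shape[2], out_data.shape[3]
    bt = astensor(b) if b is not None else None
    if bt is not None:
        out_data += bt.data.reshape(1, Co, 1, 1)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(Co, B * Ho * Wo)
        if w.requires_grad:
            w._accumulate((g2 @ cols.T).reshape(w.data.shape), own=True)
        if bt is not None and bt.requires_grad:
            bt._accumulate(g.sum(axis=(0, 2, 3)), own=True)
        if not x.requires_grad:
            return
        w2 = w.data.reshape(Co, C * kh * kw)
        dcols = (w2.T @ g2).reshape(C, kh, kw, B, Ho, Wo)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
        for ky in range(kh):
            for kx in range(kw):
                dxp[:, :, ky:ky + s * Ho:s, kx:kx + s * Wo:s] += (
                    dcols[:, ky, kx].transpose(1, 0, 2, 3))
        x._accumulate(dxp[:, :, p:p + H, p:p + W] if p else dxp, own=True)

    parents = (x, w) if bt is None else (x, w, bt)
    return _make(out_data, parents, backward)


def depthwise_conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
                     multiplier: int = 1) -> Tensor:
    """Per-channel convolution; weight (C*multiplier, 1, kh, kw).

    With multiplier m, output channel c*m+j is produced from input channel c.
    """
    x, w = astensor(x), astensor(w)
    B, C, H, W = x.data.shape
    Cm, one, kh, kw = w.data.shape
    if Cm != C * multiplier:
        raise ValueError(f"depthwise weight channels {Cm} != {C}*{multiplier}")
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xin = x.data if multiplier == 1 else np.repeat(x.data, multiplier, axis=1)
    xp = _pad_hw(xin, p)
    out_data = np.zeros((B, Cm, Ho, Wo), dtype=x.data.dtype)
    for ky in range(kh):
        for kx in range(kw):
            out_data += (w.data[:, 0, ky, kx][None, :, None, None]
                         * xp[:, :, ky:ky + s * Ho:s, kx:kx + s * Wo:s])
    bt = astensor(b) if b is not None else None
    if bt is not None:
        out_data += bt.data.reshape(1, Cm, 1, 1)

    def backward(g):
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for ky in range(kh):
                for kx in range(kw):
                    xs = xp[:, :, ky:ky + s * Ho:s, kx:kx + s * Wo:s]
                    dw[:, 0, ky, kx] = np.einsum("bchw,bchw->c", g, xs)
            w._accumulate(dw, own=True)
        if bt is not None and bt.requires_grad:
            bt._accumulate(g.sum(axis=(0, 2, 3)), own=True)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for ky in range(kh):
                for kx in range(kw):
                    dxp[:, :, ky:ky + s * Ho:s, kx:kx + s * Wo:s] += (
                        w.data[:, 0, ky, kx][None, :, None, None] * g)
            dxin = dxp[:, :, p:p + H, p:p + W] if p else dxp
            if multiplier != 1:
                dxin = dxin.reshape(B, C, multiplier, H, W).sum(axis=2)
            x._accumulate(dxin, own=True)

    parents = (x, w) if bt is None else (x, w, bt)
    return _make(out_data, parents, backward)


def maxpool2d(x, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    x = astensor(x)
    B, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s].reshape(B, C, Ho, Wo, k * k)
    arg = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
        oy, ox = np.meshgrid(np.arange(Ho) * s, np.arange(Wo) * s, indexing="ij")
        iy = oy[None, None] + arg // k
        ix = ox[None, None] + arg % k
        bidx = np.arange(B)[:, None, None, None]
        cidx = np.arange(C)[None, :, None, None]
        np.add.at(dxp, (bidx, cidx, iy, ix), g)
        x._accumulate(dxp[:, :, p:p + H, p:p + W] if p else dxp, own=True)

    return _make(np.ascontiguousarray(out_data), (x,), backward)


def upsample_nearest2x(x) -> Tensor:
    x = astensor(x)
    B, C, H, W = x.data.shape
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)), own=True)

    return _make(out_data, (x,), backward)


def global_avg_pool(x) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) spatial mean."""
    x = astensor(x)
    B, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / (H * W), x.data.shape).astype(x.data.dtype), own=True)

    return _make(out_data, (x,), backward)


def batchnorm2d(x, gamma, beta, running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Channelwise normalisation; updates running stats in place when training."""
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    B, C, H, W = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps).astype(x.data.dtype)
    xhat = (x.data - mean.reshape(1, C, 1, 1)) / std.reshape(1, C, 1, 1)
    out_data = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)), own=True)
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)), own=True)
        if x.requires_grad:
            gs = gamma.data.reshape(1, C, 1, 1) / std.reshape(1, C, 1, 1)
            if training:
                m = B * H * W
                gmean = g.mean(axis=(0, 2, 3), keepdims=True)
                gxhat = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(gs * (g - gmean - xhat * gxhat), own=True)
            else:
                x._accumulate(gs * g, own=True)

    return _make(out_data, (x, gamma, beta), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on raw logits (numerically stable)."""
    logits = astensor(logits)
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    out_data = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

    def backward(g):
        if logits.requires_grad:
            s = expit(z)
            logits._accumulate(g * (s - t), own=True)

    return _make(out_data, (logits,), backward)


class Param(Tensor):
    """Trainable tensor with an identity and weight-decay flag."""

    __slots__ = ("decay",)

    def __init__(self, data, name: str = "", decay: bool = True):
        data = np.asarray(data, dtype=DTYPE)
        super().__init__(data, requires_grad=True)
        # requires_grad must survive no_grad() construction contexts
        self.requires_grad = True
        self.name = name
        self.decay = decay

    def zero_grad(self):
        self.grad = None
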