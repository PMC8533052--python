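"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based autograd engine sized for the segmentation networks in
this package: dense 4-D feature maps, stride-1 "same" convolutions (plain,
dilated and deformable), batch normalisation, 2x2 max pooling, exact x2
bilinear upsampling, channel/spatial reductions and the elementwise algebra
needed by the Dice + binary cross-entropy objective.

Every operation builds a closure that maps the output gradient to the input
gradients; :meth:`Tensor.backward` walks the graph in reverse topological
order.  All computation is plain NumPy (float32 by default), so results are
bit-reproducible for a fixed seed on a fixed platform.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_float(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable]] = ()):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents) if _GRAD_ENABLED else ()
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in self._parents)

    # -- graph ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs here can be a few hundred nodes deep)
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
            for parent, _ in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, grad_fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = grad_fn(g)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def sum(self) -> "Tensor":
        return tsum(self)

    def mean(self) -> "Tensor":
        return tmean(self)

    def reshape(self, *shape) -> "Tensor":
        return reshape(self, shape if len(shape) > 1 else shape[0])

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
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _sum_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data + b.data
    return Tensor(out, parents=[
        (a, lambda g: _sum_to(g, a.data.shape)),
        (b, lambda g: _sum_to(g, b.data.shape)),
    ])


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data * b.data
    return Tensor(out, parents=[
        (a, lambda g: _sum_to(g * b.data, a.data.shape)),
        (b, lambda g: _sum_to(g * a.data, b.data.shape)),
    ])


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data / b.data
    return Tensor(out, parents=[
        (a, lambda g: _sum_to(g / b.data, a.data.shape)),
        (b, lambda g: _sum_to(-g * a.data / (b.data * b.data), b.data.shape)),
    ])


def log(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.data), parents=[(a, lambda g: g / a.data)])


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through gradient inside the open interval."""
    a = astensor(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)
    return Tensor(out, parents=[(a, lambda g: g * mask)])


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, parents=[(a, lambda g: g * mask)])


def sigmoid(a) -> Tensor:
    a = astensor(a)
    x = a.data
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return Tensor(out, parents=[(a, lambda g: g * out * (1.0 - out))])


def tsum(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.asarray(a.data.sum(), dtype=a.data.dtype),
                  parents=[(a, lambda g: np.broadcast_to(g, a.data.shape).copy())])


def tmean(a) -> Tensor:
    a = astensor(a)
    n = a.data.size
    return Tensor(np.asarray(a.data.mean(), dtype=a.data.dtype),
                  parents=[(a, lambda g: np.broadcast_to(g / n, a.data.shape).copy())])


def sum_per_sample(a) -> Tensor:
    """Sum over all but the leading (batch) axis: (N, ...) -> (N,)."""
    a = astensor(a)
    n = a.data.shape[0]
    out = a.data.reshape(n, -1).sum(axis=1)

    def grad_a(g):
        return np.broadcast_to(g.reshape((n,) + (1,) * (a.data.ndim - 1)),
                               a.data.shape).copy()

    return Tensor(out, parents=[(a, grad_a)])


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    orig = a.data.shape
    return Tensor(a.data.reshape(shape),
                  parents=[(a, lambda g: g.reshape(orig))])


# ---------------------------------------------------------------------------
# convolution (stride 1, symmetric zero padding, optional dilation)
# ---------------------------------------------------------------------------

def _conv_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
              padding: int, dilation: int) -> np.ndarray:
    """Stride-1 convolution as a sum of per-tap channel matmuls.

    Avoids the im2col patch copy: for each kernel tap the (Cout, Cin) slice
    multiplies the whole padded image in one GEMM and the result is
    accumulated from a shifted window.
    """
    cout, cin, k, _ = w.shape
    n, c, h, w_ = x.shape
    p, d = padding, dilation
    ho = h + 2 * p - d * (k - 1)
    wo = w_ + 2 * p - d * (k - 1)
    if p:
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    else:
        xp = x
    hp, wp = xp.shape[2], xp.shape[3]
    if k == 1:
        y = (np.ascontiguousarray(w[:, :, 0, 0]) @ xp.reshape(n, c, -1)
             ).reshape(n, cout, ho, wo)
    elif c * k * k <= 48:
        # few input channels: the patch matrix is small, one GEMM beats taps
        eff = (k - 1) * d + 1
        v = sliding_window_view(xp, (eff, eff), axis=(2, 3))[..., ::d, ::d]
        cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n, ho, wo, c * k * k)
        y = np.ascontiguousarray(
            (cols @ w.reshape(cout, -1).T).transpose(0, 3, 1, 2))
    else:
        xpr = xp.reshape(n, c, hp * wp)
        y = np.zeros((n, cout, ho, wo), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                t = (np.ascontiguousarray(w[:, :, i, j]) @ xpr
                     ).reshape(n, cout, hp, wp)
                y += t[:, :, i * d:i * d + ho, j * d:j * d + wo]
    if b is not None:
        y += b[None, :, None, None]
    return y


def _conv_grad_w(g: np.ndarray, x: np.ndarray, k: int,
                 padding: int, dilation: int) -> np.ndarray:
    """Kernel gradient: per-tap contraction of output grad with shifted input."""
    n, cout, ho, wo = g.shape
    cin = x.shape[1]
    p, d = padding, dilation
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    if k == 1:
        gw = np.tensordot(g, xp, axes=([0, 2, 3], [0, 2, 3]))
        return gw.reshape(cout, cin, 1, 1)
    gt = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
    dw = np.empty((cout, cin, k, k), dtype=g.dtype)
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i * d:i * d + ho, j * d:j * d + wo]
            xs2 = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(cin, -1)
            dw[:, :, i, j] = gt @ xs2.T
    return dw


def conv2d(x, weight, bias=None, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, stride 1.  ``weight`` is (Cout, Cin, k, k).

    Only "same"-style paddings with ``padding <= dilation*(k-1)`` are
    supported, which covers every convolution in the network and keeps the
    input gradient expressible as a (transposed) convolution of the output
    gradient — no scatter-adds on the hot path.
    """
    x, weight = astensor(x), astensor(weight)
    bias = astensor(bias) if bias is not None else None
    cout, cin, k, _ = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(
            f"conv2d: input has {x.data.shape[1]} channels, weight expects {cin}")
    if padding > dilation * (k - 1):
        raise ValueError("conv2d supports padding <= dilation*(k-1)")
    out = _conv_raw(x.data, weight.data,
                    bias.data if bias is not None else None,
                    padding, dilation)

    def grad_x(g):
        # transposed convolution: full-correlation with the flipped kernel
        w_t = np.ascontiguousarray(
            weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        p_t = dilation * (k - 1) - padding
        return _conv_raw(g, w_t, None, p_t, dilation)

    parents = [(x, grad_x),
               (weight, lambda g: _conv_grad_w(g, x.data, k, padding, dilation))]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=parents)


# ---------------------------------------------------------------------------
# deformable convolution (3x3, stride 1, padding 1)
# ---------------------------------------------------------------------------

try:  # numba accelerates the input-gradient scatter; required at runtime
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    _njit = None


def _scatter_bilinear_py(dx, nn_, lin, wgt, ds):
    m, four = lin.shape
    for i in range(m):
        n = nn_[i]
        for c4 in range(four):
            w = wgt[i, c4]
            if w != 0.0:
                dx[n, lin[i, c4], :] += w * ds[i, :]


if _njit is not None:
    _scatter_bilinear = _njit(cache=False, fastmath=True)(_scatter_bilinear_py)
else:  # pragma: no cover
    _scatter_bilinear = _scatter_bilinear_py

_TAP_R = np.repeat(np.arange(-1, 2), 3).astype(np.float32)      # (9,)
_TAP_S = np.tile(np.arange(-1, 2), 3).astype(np.float32)        # (9,)


def deform_conv2d(x, offsets, weight, bias=None) -> Tensor:
    """3x3 deformable convolution, stride 1, zero padding 1.

    ``offsets`` is (N, 18, H, W): per output location, 9 (dy, dx) pairs that
    displace the kernel taps; sampling is bilinear with zeros outside the
    image.  With all offsets zero this is exactly a standard 3x3 convolution.
    """
    x, offsets, weight = astensor(x), astensor(offsets), astensor(weight)
    bias = astensor(bias) if bias is not None else None
    n, c, h, w_ = x.data.shape
    cout = weight.data.shape[0]
    if offsets.data.shape != (n, 18, h, w_):
        raise ValueError(f"offsets shape {offsets.data.shape} != {(n, 18, h, w_)}")

    off = offsets.data.reshape(n, 9, 2, h, w_)
    ii = np.arange(h, dtype=np.float32)[None, None, :, None]
    jj = np.arange(w_, dtype=np.float32)[None, None, None, :]
    py = ii + _TAP_R[None, :, None, None] + off[:, :, 0]   # (N,9,H,W)
    px = jj + _TAP_S[None, :, None, None] + off[:, :, 1]

    y0 = np.floor(py)
    x0 = np.floor(px)
    ay = py - y0
    ax = px - x0
    y0 = y0.astype(np.int64)
    x0 = x0.astype(np.int64)
    y1, x1 = y0 + 1, x0 + 1

    corners = []  # (lin_index, bilinear_weight, validity) per corner
    for yc, xc, wy, wx in ((y0, x0, 1 - ay, 1 - ax), (y0, x1, 1 - ay, ax),
                           (y1, x0, ay, 1 - ax), (y1, x1, ay, ax)):
        valid = (yc >= 0) & (yc < h) & (xc >= 0) & (xc < w_)
        lin = np.clip(yc, 0, h - 1) * w_ + np.clip(xc, 0, w_ - 1)
        corners.append((lin, (wy * wx * valid).astype(x.data.dtype), valid))

    xf = x.data.reshape(n, c, h * w_)
    n_idx = np.arange(n)[:, None, None, None]
    vals = []                                  # gathered corner values (N,9,H,W,C)
    sampled = np.zeros((n, 9, h, w_, c), dtype=x.data.dtype)
    for lin, wgt, valid in corners:
        v = xf[n_idx, :, lin] * valid[..., None]
        vals.append(v)
        sampled += wgt[..., None] * v

    cols = sampled.transpose(0, 2, 3, 4, 1).reshape(n, h, w_, c * 9)
    wr = weight.data.reshape(cout, -1)
    y = cols @ wr.T
    if bias is not None:
        y = y + bias.data
    out = np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def _dsampled(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        dcols = (g2 @ wr).reshape(n, h, w_, c, 9)
        return dcols.transpose(0, 4, 1, 2, 3)          # (N,9,H,W,C)

    def grad_x(g):
        ds = _dsampled(g).reshape(-1, c)
        lin_m = np.stack([lin.reshape(-1) for lin, _, _ in corners], axis=1)
        wgt_m = np.stack([wgt.reshape(-1) for _, wgt, _ in corners], axis=1)
        n_flat = np.broadcast_to(n_idx, (n, 9, h, w_)).reshape(-1)
        dxt = np.zeros((n, h * w_, c), dtype=x.data.dtype)
        _scatter_bilinear(dxt, n_flat, lin_m,
                          np.ascontiguousarray(wgt_m),
                          np.ascontiguousarray(ds))
        return np.ascontiguousarray(dxt.transpose(0, 2, 1)).reshape(n, c, h, w_)

    def grad_offsets(g):
        ds = _dsampled(g)
        v00, v01, v10, v11 = vals
        dpy = (((v10 - v00) * (1 - ax)[..., None] +
                (v11 - v01) * ax[..., None]) * ds).sum(-1)
        dpx = (((v01 - v00) * (1 - ay)[..., None] +
                (v11 - v10) * ay[..., None]) * ds).sum(-1)
        doff = np.stack([dpy, dpx], axis=2)            # (N,9,2,H,W)
        return doff.reshape(n, 18, h, w_)

    def grad_w(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        return (g2.T @ cols.reshape(-1, c * 9)).reshape(weight.data.shape)

    parents = [(x, grad_x), (offsets, grad_offsets), (weight, grad_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=parents)


# ---------------------------------------------------------------------------
# normalisation, pooling, resampling
# ---------------------------------------------------------------------------

def batchnorm2d(x, gamma, beta, running_mean, running_var, *, training: bool,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    In training mode the running statistics are updated in place (biased
    variance for normalisation, unbiased for the running estimate).
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    xd = x.data
    n, c, h, w_ = xd.shape
    if training:
        m = n * h * w_
        mu = xd.mean(axis=(0, 2, 3))
        var = np.einsum("nchw,nchw->c", xd, xd) / m - mu * mu
        np.maximum(var, 0.0, out=var)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def grad_x(g):
        gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
        if not training:
            return g * gi
        m = n * h * w_
        gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
        gxhat = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        del m
        return gi * (g - gmean - xhat * gxhat)

    return Tensor(out, parents=[
        (x, grad_x),
        (gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
        (beta, lambda g: g.sum(axis=(0, 2, 3))),
    ])


def maxpool2x2(x) -> Tensor:
    x = astensor(x)
    n, c, h, w_ = x.data.shape
    if h % 2 or w_ % 2:
        raise ValueError(f"maxpool2x2 needs even dims, got {h}x{w_}")
    v = x.data.reshape(n, c, h // 2, 2, w_ // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(v).reshape(n, c, h // 2, w_ // 2, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def grad_x(g):
        z = np.zeros_like(v)
        np.put_along_axis(z, idx[..., None], g[..., None], axis=-1)
        z = z.reshape(n, c, h // 2, w_ // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(z).reshape(n, c, h, w_)

    return Tensor(out, parents=[(x, grad_x)])


def _up_axis_last(a: np.ndarray) -> np.ndarray:
    """Double the last axis with the 2x bilinear stencil (edge-clamped)."""
    out = np.empty(a.shape[:-1] + (2 * a.shape[-1],), dtype=a.dtype)
    even, odd = out[..., 0::2], out[..., 1::2]
    np.multiply(a, 0.75, out=even)
    even[..., 1:] += 0.25 * a[..., :-1]
    even[..., 0] += 0.25 * a[..., 0]
    np.multiply(a, 0.75, out=odd)
    odd[..., :-1] += 0.25 * a[..., 1:]
    odd[..., -1] += 0.25 * a[..., -1]
    return out


def _down_axis_last(g: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_up_axis_last`."""
    ge, go = g[..., 0::2], g[..., 1::2]
    dx = 0.75 * (ge + go)
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., 0] += 0.25 * ge[..., 0]
    dx[..., -1] += 0.25 * go[..., -1]
    return dx


def upsample2x(x) -> Tensor:
    """Bilinear x2 upsampling of (N, C, H, W), half-pixel-centre convention."""
    x = astensor(x)

    def fwd(a):
        a = _up_axis_last(a)                    # width
        a = _up_axis_last(a.swapaxes(-1, -2))   # height
        return np.ascontiguousarray(a.swapaxes(-1, -2))

    def grad_x(g):
        g = _down_axis_last(np.ascontiguousarray(g.swapaxes(-1, -2)))
        g = _down_axis_last(np.ascontiguousarray(g.swapaxes(-1, -2)))
        return g

    return Tensor(fwd(x.data), parents=[(x, grad_x)])


# ---------------------------------------------------------------------------
# reductions over channels / space, concatenation, dense layer
# ---------------------------------------------------------------------------

def channel_max(x) -> Tensor:
    """Per-position maximum over channels: (N,C,H,W) -> (N,1,H,W)."""
    x = astensor(x)
    idx = x.data.argmax(axis=1)

    def grad_x(g):
        z = np.zeros_like(x.data)
        np.put_along_axis(z, idx[:, None], g, axis=1)
        return z

    return Tensor(np.take_along_axis(x.data, idx[:, None], axis=1),
                  parents=[(x, grad_x)])


def channel_mean(x) -> Tensor:
    """Per-position mean over channels: (N,C,H,W) -> (N,1,H,W)."""
    x = astensor(x)
    c = x.data.shape[1]
    return Tensor(x.data.mean(axis=1, keepdims=True),
                  parents=[(x, lambda g: np.broadcast_to(g / c, x.data.shape).copy())])


def global_max(x) -> Tensor:
    """Global spatial max pool: (N,C,H,W) -> (N,C,1,1)."""
    x = astensor(x)
    n, c, h, w_ = x.data.shape
    flat = x.data.reshape(n, c, -1)
    idx = flat.argmax(axis=-1)

    def grad_x(g):
        z = np.zeros_like(flat)
        np.put_along_axis(z, idx[..., None], g.reshape(n, c, 1), axis=-1)
        return z.reshape(x.data.shape)

    return Tensor(np.take_along_axis(flat, idx[..., None], axis=-1).reshape(n, c, 1, 1),
                  parents=[(x, grad_x)])


def global_mean(x) -> Tensor:
    """Global spatial average pool: (N,C,H,W) -> (N,C,1,1)."""
    x = astensor(x)
    n, c, h, w_ = x.data.shape
    return Tensor(x.data.mean(axis=(2, 3), keepdims=True),
                  parents=[(x, lambda g: np.broadcast_to(
                      g / (h * w_), x.data.shape).copy())])


def concat_channels(tensors: Sequence) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[1] for t in tensors]
    bounds = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=1)

    def make_grad(i):
        lo, hi = bounds[i], bounds[i + 1]
        return lambda g: np.ascontiguousarray(g[:, lo:hi])

    return Tensor(out, parents=[(t, make_grad(i)) for i, t in enumerate(tensors)])


def linear(x, weight, bias=None) -> Tensor:
    """Dense layer: (N, Fin) @ weight.T + bias, weight is (Fout, Fin)."""
    x, weight = astensor(x), astensor(weight)
    bias = astensor(bias) if bias is not None else None
    out = x.data @ weight.data.T
    if bias is not None:
        out = out + bias.data
    parents = [(x, lambda g: g @ weight.data),
               (weight, lambda g: g.T @ x.data)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=0)))
    return Tensor(out, parents=parents)
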