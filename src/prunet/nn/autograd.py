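"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape: each operation returns a :class:`Tensor` whose
``_backward`` closure scatters the output gradient into its parents. The op
set covers exactly what the segmentation networks need — 2-D convolution
(stride 1, same padding, via im2col), 2x2 stride-2 transposed convolution,
batch normalisation, max pooling by integer factors, bilinear upsampling by
integer factors, channel/spatial reductions, elementwise arithmetic and the
sigmoid/ReLU nonlinearities.

The default array dtype is float32; :func:`set_default_dtype` switches new
tensors to float64 (used by gradient checks that compare against finite
differences).
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_DTYPE = np.float32
_GRAD_ENABLED = True


def set_default_dtype(dtype) -> None:
    """Set the dtype used for newly created tensors (float32 or float64)."""
    global _DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("default dtype must be float32 or float64")
    _DTYPE = dtype.type


def default_dtype():
    return _DTYPE


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward = None

    # -- convenience -------------------------------------------------------
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

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
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

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out.requires_grad = req
    out._parents = tuple(parents) if req else ()
    out._backward = backward if req else None
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        _accumulate(x, g * mask)

    out = _make(out_data, (x,), backward)
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    d = x.data
    out_data = np.empty_like(d)
    pos = d >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ed = np.exp(d[~pos])
    out_data[~pos] = ed / (1.0 + ed)

    def backward(g):
        _accumulate(x, g * out_data * (1.0 - out_data))

    out = _make(out_data, (x,), backward)
    return out


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            shape = list(x.data.shape)
            for ax in axes:
                shape[ax] = 1
            g = g.reshape(shape)
        _accumulate(x, np.broadcast_to(g, x.data.shape).astype(x.data.dtype))

    out = _make(np.asarray(out_data), (x,), backward)
    return out


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, g in zip(ts, parts):
            _accumulate(t, g)

    out = _make(out_data, ts, backward)
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _same_pads(k: int) -> tuple[int, int]:
    """Leading/trailing padding preserving size at stride 1 (asymmetric for even k)."""
    return (k - 1) // 2, k - 1 - (k - 1) // 2


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (C*k*k, N*H*W) patch matrix under same-padding."""
    p0, p1 = _same_pads(k)
    if k > 1:
        x = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    n, c, h, w = v.shape[:4]
    cols = v.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    n, c, h, w = x_shape
    p0, p1 = _same_pads(k)
    d = dcols.reshape(c, k, k, n, h, w).transpose(3, 0, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + p0 + p1, w + p0 + p1), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += d[:, :, i, j]
    if k > 1:
        return dxp[:, :, p0:p0 + h, p0:p0 + w]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 convolution; w has shape (Co, Ci, k, k)."""
    n, ci, h, wd = x.data.shape
    co, ci_w, k, _ = w.data.shape
    if ci != ci_w:
        raise ValueError(f"conv2d channel mismatch: input {ci}, weight {ci_w}")
    cols = _im2col(x.data, k)                           # (Ci*k*k, N*H*W)
    wm = w.data.reshape(co, -1)
    out_data = (wm @ cols).reshape(co, n, h * wd).transpose(1, 0, 2).reshape(n, co, h, wd)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(co, -1)
        if w.requires_grad:
            _accumulate(w, (gm @ cols.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = wm.T @ gm
            _accumulate(x, _col2im(dcols, x.data.shape, k))

    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, backward)
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2 transposed convolution with a 2x2 kernel (Ci, Co, 2, 2)."""
    n, ci, h, wd = x.data.shape
    ci_w, co = w.data.shape[:2]
    if ci != ci_w:
        raise ValueError(f"conv_transpose2x2 channel mismatch: {ci} vs {ci_w}")
    t = np.tensordot(x.data, w.data, axes=([1], [0]))    # (N,H,W,Co,2,2)
    out_data = np.ascontiguousarray(
        t.transpose(0, 3, 1, 4, 2, 5)).reshape(n, co, 2 * h, 2 * wd)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gb = g.reshape(n, co, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        # gb: (N,H,W,Co,2,2)
        if w.requires_grad:
            dw = np.tensordot(x.data, gb, axes=([0, 2, 3], [0, 1, 2]))
            _accumulate(w, dw)                            # (Ci,Co,2,2)
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = np.tensordot(gb, w.data, axes=([3, 4, 5], [1, 2, 3]))
            _accumulate(x, dx.transpose(0, 3, 1, 2))
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, backward)
    return out


# ---------------------------------------------------------------------------
# normalisation, pooling, resampling
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) * invstd.reshape(1, -1, 1, 1)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accumulate(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data.reshape(1, -1, 1, 1) * invstd.reshape(1, -1, 1, 1)
            if training:
                dxhat = g * gamma.data.reshape(1, -1, 1, 1)
                m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = invstd.reshape(1, -1, 1, 1) * (dxhat - m1 - xhat * m2)
            else:
                dx = g * gs
            _accumulate(x, dx.astype(x.data.dtype))

    out = _make(out_data, (x, gamma, beta), backward)
    return out


def max_pool(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.data.shape
    f = factor
    if h % f or w % f:
        raise ValueError(f"max_pool: spatial dims {(h, w)} not divisible by {f}")
    ho, wo = h // f, w // f
    v = x.data.reshape(n, c, ho, f, wo, f).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, f * f)
    idx = v.argmax(axis=-1)
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dv = np.zeros_like(v)
        np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
        dx = dv.reshape(n, c, ho, wo, f, f).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        _accumulate(x, dx)

    out = _make(np.ascontiguousarray(out_data), (x,), backward)
    return out


_INTERP_CACHE: dict = {}


def _interp_matrix(n_in: int, factor: int, dtype) -> np.ndarray:
    key = (n_in, factor, np.dtype(dtype).str)
    m = _INTERP_CACHE.get(key)
    if m is None:
        n_out = n_in * factor
        dst = np.arange(n_out)
        src = np.clip((dst + 0.5) / factor - 0.5, 0.0, n_in - 1.0)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w1 = src - i0
        m = np.zeros((n_out, n_in), dtype=dtype)
        np.add.at(m, (dst, i0), 1.0 - w1)
        np.add.at(m, (dst, i1), w1)
        _INTERP_CACHE[key] = m
    return m


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.data.shape
    mh = _interp_matrix(h, factor, x.data.dtype)
    mw = _interp_matrix(w, factor, x.data.dtype)
    t = np.tensordot(x.data, mh, axes=([2], [1]))        # (N,C,W,Ho)
    out_data = np.ascontiguousarray(
        np.tensordot(t, mw, axes=([2], [1])).transpose(0, 1, 2, 3))  # (N,C,Ho,Wo)

    def backward(g):
        t2 = np.tensordot(g, mh, axes=([2], [0]))         # (N,C,Wo,H)
        dx = np.tensordot(t2, mw, axes=([2], [0]))        # (N,C,H,W)
        _accumulate(x, np.ascontiguousarray(dx))

    out = _make(out_data, (x,), backward)
    return out


# ---------------------------------------------------------------------------
# reductions used by attention
# ---------------------------------------------------------------------------

def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        _accumulate(x, np.broadcast_to(g / (h * w), x.data.shape).astype(x.data.dtype))

    out = _make(out_data, (x,), backward)
    return out


def global_max_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1).reshape(n, c, 1, 1)

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g.reshape(n, c, 1), axis=-1)
        _accumulate(x, dflat.reshape(x.data.shape))

    out = _make(out_data, (x,), backward)
    return out


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[1]
    out_data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        _accumulate(x, np.broadcast_to(g / c, x.data.shape).astype(x.data.dtype))

    out = _make(out_data, (x,), backward)
    return out


def channel_max(x: Tensor) -> Tensor:
    idx = x.data.argmax(axis=1)
    out_data = np.take_along_axis(x.data, idx[:, None], axis=1)

    def backward(g):
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, idx[:, None], g, axis=1)
        _accumulate(x, dx)

    out = _make(out_data, (x,), backward)
    return out
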