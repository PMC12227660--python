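"""Reverse-mode automatic differentiation on numpy arrays.

A small dynamic-tape engine: every operation builds a :class:`Tensor` that
remembers its parents and a closure computing parent gradients.  All data is
float64, which keeps finite-difference gradient checks tight (the bounding-box
loss family is verified against numerical gradients at 1e-4 relative error).

Only the operations the detector needs are implemented; convolution and
pooling are primitives with hand-written backward passes (im2col-style), the
rest compose from elementwise primitives.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "concat", "maximum", "minimum", "exp", "log",
    "sqrt", "sigmoid", "relu", "silu", "softplus", "arctan", "stack",
    "conv2d", "conv1d_circular", "maxpool2d", "avgpool_grid",
    "global_avgpool", "resize_nearest", "pad2d",
]


class Tensor:
    """A numpy array with gradient tracking.

    Parameters never require broadcasting tricks from callers: elementwise ops
    broadcast like numpy and gradients are summed back to each parent's shape.
    """

    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    # make numpy defer to Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._bw = _bw if self.requires_grad else None
        self.grad = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = grad
        for t in reversed(topo):
            if t._bw is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._bw(t.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(g, parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        return Tensor(self.data + o.data, _parents=(self, o),
                      _bw=lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _bw=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor(self.data * o.data, _parents=(self, o),
                      _bw=lambda g: (g * o.data, g * self.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor(self.data / o.data, _parents=(self, o),
                      _bw=lambda g: (g / o.data, -g * self.data / o.data ** 2))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        return Tensor(self.data ** p, _parents=(self,),
                      _bw=lambda g: (g * p * self.data ** (p - 1),))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(self.data.reshape(shape), _parents=(self,),
                      _bw=lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), _parents=(self,),
                      _bw=lambda g: (g.transpose(inv),))

    def __getitem__(self, key):
        out = self.data[key]

        def bw(g):
            dx = np.zeros_like(self.data)
            np.add.at(dx, key, g)
            return (dx,)

        return Tensor(out, _parents=(self,), _bw=bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, shape).copy(),)

        return Tensor(out, _parents=(self,), _bw=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise functions ----------------------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return Tensor(out, _parents=(x,), _bw=lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.log(x.data), _parents=(x,), _bw=lambda g: (g / x.data,))


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.sqrt(x.data)
    return Tensor(out, _parents=(x,), _bw=lambda g: (g * 0.5 / out,))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out, _parents=(x,), _bw=lambda g: (g * out * (1 - out),))


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return Tensor(x.data * mask, _parents=(x,), _bw=lambda g: (g * mask,))


def silu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = x.data * s
    return Tensor(out, _parents=(x,), _bw=lambda g: (g * (s + out * (1 - s)),))


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), numerically stable; gradient is sigmoid(x)."""
    x = as_tensor(x)
    out = np.logaddexp(0.0, x.data)
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out, _parents=(x,), _bw=lambda g: (g * s,))


def arctan(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.arctan(x.data), _parents=(x,),
                  _bw=lambda g: (g / (1.0 + x.data ** 2),))


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.maximum(a.data, b.data)
    # ties split evenly so the subgradient is symmetric
    ga = (a.data > b.data) + 0.5 * (a.data == b.data)
    return Tensor(out, _parents=(a, b),
                  _bw=lambda g: (g * ga, g * (1.0 - ga)))


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.minimum(a.data, b.data)
    ga = (a.data < b.data) + 0.5 * (a.data == b.data)
    return Tensor(out, _parents=(a, b),
                  _bw=lambda g: (g * ga, g * (1.0 - ga)))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    return Tensor(out, _parents=tuple(tensors),
                  _bw=lambda g: tuple(np.split(g, splits, axis=axis)))


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)
    return Tensor(out, _parents=tuple(tensors),
                  _bw=lambda g: tuple(np.moveaxis(g, axis, 0)))


# -- structured primitives -----------------------------------------------------

def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of an NCHW tensor."""
    x = as_tensor(x)
    if pad == 0:
        return x
    out = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return Tensor(out, _parents=(x,),
                  _bw=lambda g: (g[:, :, pad:-pad, pad:-pad],))


def pad2d_edge1(x: Tensor) -> Tensor:
    """Replicate-pad the spatial axes of NCHW by one pixel.

    Used by the fixed Sobel stencils so that a constant image produces an
    exactly zero edge response everywhere, including the border.
    """
    x = as_tensor(x)
    out = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")

    def bw(g):
        gx = g[:, :, 1:-1, 1:-1].copy()
        gx[:, :, 0, :] += g[:, :, 0, 1:-1]
        gx[:, :, -1, :] += g[:, :, -1, 1:-1]
        gx[:, :, :, 0] += g[:, :, 1:-1, 0]
        gx[:, :, :, -1] += g[:, :, 1:-1, -1]
        gx[:, :, 0, 0] += g[:, :, 0, 0]
        gx[:, :, 0, -1] += g[:, :, 0, -1]
        gx[:, :, -1, 0] += g[:, :, -1, 0]
        gx[:, :, -1, -1] += g[:, :, -1, -1]
        return (gx,)

    return Tensor(out, _parents=(x,), _bw=bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW; weight (O, C//groups, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    assert C == Cg * groups and O % groups == 0
    Og = O // groups
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (N, C, Ho, Wo, kh, kw) view
    out = np.empty((N, O, Ho, Wo))
    for g in range(groups):
        wg = w.data[g * Og:(g + 1) * Og]             # (Og, Cg, kh, kw)
        vg = win[:, g * Cg:(g + 1) * Cg]
        # contract (Cg, kh, kw) -> (N, Ho, Wo, Og)
        r = np.tensordot(vg, wg, axes=([1, 4, 5], [1, 2, 3]))
        out[:, g * Og:(g + 1) * Og] = np.moveaxis(r, 3, 1)
    if b is not None:
        out += as_tensor(b).data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, as_tensor(b))

    def bw(gout):
        # gout: (N, O, Ho, Wo)
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for g in range(groups):
            go = gout[:, g * Og:(g + 1) * Og]        # (N, Og, Ho, Wo)
            vg = win[:, g * Cg:(g + 1) * Cg]
            gw[g * Og:(g + 1) * Og] = np.tensordot(
                go, vg, axes=([0, 2, 3], [0, 2, 3]))
            # gradient w.r.t. the padded input, folded window by window
            wg = w.data[g * Og:(g + 1) * Og]
            gc = np.tensordot(go, wg, axes=([1], [0]))   # (N,Ho,Wo,Cg,kh,kw)
            gc = np.moveaxis(gc, 3, 1)                   # (N,Cg,Ho,Wo,kh,kw)
            sl = slice(g * Cg, (g + 1) * Cg)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, sl, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += gc[..., i, j]
        gx = gxp if padding == 0 else gxp[:, :, padding:-padding, padding:-padding]
        if b is None:
            return gx, gw
        return gx, gw, gout.sum(axis=(0, 2, 3))

    return Tensor(out, _parents=parents, _bw=bw)


def batchnorm2d(x: Tensor, weight: Tensor, bias: Tensor, running_mean: np.ndarray,
                running_var: np.ndarray, training: bool, eps: float = 1e-5,
                momentum: float = 0.1) -> Tensor:
    """Fused batch normalization over (N, H, W) per channel.

    Updates the running statistics in place when ``training`` is True.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = weight.data[None, :, None, None] * xhat + bias.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bw(g):
        gbias = g.sum(axis=(0, 2, 3))
        gweight = (g * xhat).sum(axis=(0, 2, 3))
        gxhat = g * weight.data[None, :, None, None]
        if training:
            gx = (inv[None, :, None, None] / m) * (
                m * gxhat
                - gxhat.sum(axis=(0, 2, 3))[None, :, None, None]
                - xhat * (gxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None])
        else:
            gx = gxhat * inv[None, :, None, None]
        return gx, gweight, gbias

    return Tensor(out, _parents=(x, weight, bias), _bw=bw)


def conv1d_circular(x: Tensor, k: Tensor) -> Tensor:
    """Shared 1-D cross-correlation along the last axis with circular padding.

    x: (..., C) channel sequences, k: (ks,) odd-length kernel.
    """
    x, k = as_tensor(x), as_tensor(k)
    ks = k.data.shape[0]
    assert ks % 2 == 1
    p = ks // 2
    xp = np.concatenate([x.data[..., -p:], x.data, x.data[..., :p]], axis=-1)
    win = np.lib.stride_tricks.sliding_window_view(xp, ks, axis=-1)  # (..., C, ks)
    out = win @ k.data

    def bw(g):
        gk = np.tensordot(g, win, axes=(tuple(range(g.ndim)), tuple(range(g.ndim))))
        gp = np.pad(g, [(0, 0)] * (g.ndim - 1) + [(p, p)], mode="wrap")
        gwin = np.lib.stride_tricks.sliding_window_view(gp, ks, axis=-1)
        gx = gwin @ k.data[::-1].copy()
        return gx, gk

    return Tensor(out, _parents=(x, k), _bw=bw)


def maxpool2d(x: Tensor, k: int, stride: int | None = None, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    stride = stride or k
    N, C, H, W = x.data.shape
    if padding:
        xp = np.full((N, C, H + 2 * padding, W + 2 * padding), -np.inf)
        xp[:, :, padding:-padding, padding:-padding] = x.data
    else:
        xp = x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (N,C,Ho,Wo,k,k)
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(N, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                m = (idx == i * k + j)
                gxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += g * m
        if padding:
            return (gxp[:, :, padding:-padding, padding:-padding],)
        return (gxp,)

    return Tensor(out, _parents=(x,), _bw=bw)


def avgpool_grid(x: Tensor, k: int) -> Tensor:
    """Adaptive average pooling of NCHW to a k-by-k spatial grid (LAP)."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    if k > min(H, W):
        raise ValueError(f"local grid {k} exceeds spatial size {(H, W)}")
    re = np.floor(np.arange(k + 1) * H / k).astype(int)
    ce = np.floor(np.arange(k + 1) * W / k).astype(int)
    out = np.empty((N, C, k, k))
    for i in range(k):
        for j in range(k):
            out[:, :, i, j] = x.data[:, :, re[i]:re[i + 1], ce[j]:ce[j + 1]].mean(axis=(2, 3))

    def bw(g):
        gx = np.zeros_like(x.data)
        for i in range(k):
            for j in range(k):
                n = (re[i + 1] - re[i]) * (ce[j + 1] - ce[j])
                gx[:, :, re[i]:re[i + 1], ce[j]:ce[j + 1]] += g[:, :, i, j, None, None] / n
        return (gx,)

    return Tensor(out, _parents=(x,), _bw=bw)


def global_avgpool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=True)


def resize_nearest(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Nearest-neighbour resize of the two trailing axes of NCHW (de-pooling)."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    Ho, Wo = size
    ri = np.floor(np.arange(Ho) * H / Ho).astype(int)
    ci = np.floor(np.arange(Wo) * W / Wo).astype(int)
    out = x.data[:, :, ri[:, None], ci[None, :]]

    def bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), ri[:, None], ci[None, :]), g)
        return (gx,)

    return Tensor(out, _parents=(x,), _bw=bw)
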