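"""Minimal reverse-mode autodiff for 3-D convolutional networks on NumPy.

Tensors wrap ndarrays of shape (C, X, Y, Z) (or any shape for loss
arithmetic) and record a tape of parent links; ``Tensor.backward`` runs a
topological sweep.  Convolutions use im2col / matmul so the heavy lifting
lands in BLAS; the convolution input gradient is computed as a
zero-stuffed full convolution with the spatially flipped kernel, which
avoids Python-level scatter loops.

Only the operations the segmentation network needs are implemented:
conv3d (stride 1 or 2, 'same' padding), instance norm, leaky ReLU,
nearest-neighbor upsampling, channel concatenation, dropout, sigmoid,
channel softmax, and elementwise arithmetic / reductions for losses.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv3d", "instance_norm", "leaky_relu",
           "upsample_nearest", "concat", "dropout", "sigmoid", "softmax_channels",
           "log", "clamp_min", "add", "sub", "mul", "div", "sum_", "mean_"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # convenience operators for loss arithmetic -----------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, name=""):
        super().__init__(np.asarray(data), requires_grad=True, name=name)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g, shape):
    """Reduce a gradient back to ``shape`` after NumPy broadcasting."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic & reductions (loss plumbing)
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = bw
    return out


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    out._backward = bw
    return out


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = bw
    return out


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    out._backward = bw
    return out


def log(a):
    a = _as_tensor(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = bw
    return out


def clamp_min(a, lo):
    a = _as_tensor(a)
    out = Tensor(np.maximum(a.data, lo), parents=(a,))
    mask = a.data > lo

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    out._backward = bw
    return out


def sum_(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bw(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            for ax in sorted(a_ % a.data.ndim for a_ in axes):
                g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.shape))

    out._backward = bw
    return out


def mean_(a, axis=None):
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod([a.shape[ax] for ax in
                                                  ((axis,) if np.isscalar(axis) else axis)])
    return mul(sum_(a, axis=axis), 1.0 / float(n))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def leaky_relu(x, negative_slope=0.01):
    x = _as_tensor(x)
    out = Tensor(np.where(x.data >= 0, x.data, negative_slope * x.data), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.where(x.data >= 0, g, negative_slope * g))

    out._backward = bw
    return out


def sigmoid(x):
    x = _as_tensor(x)
    p = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(p, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * p * (1.0 - p))

    out._backward = bw
    return out


def softmax_channels(x):
    """Softmax over axis 0 (the channel axis)."""
    x = _as_tensor(x)
    m = x.data.max(axis=0, keepdims=True)
    e = np.exp(x.data - m)
    p = e / e.sum(axis=0, keepdims=True)
    out = Tensor(p, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(p * (g - (p * g).sum(axis=0, keepdims=True)))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors):
    """Concatenate along the channel axis (axis 0)."""
    ts = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=0), parents=tuple(ts))
    sizes = [t.shape[0] for t in ts]

    def bw(g):
        pos = 0
        for t, s in zip(ts, sizes):
            if t.requires_grad:
                t._accumulate(g[pos : pos + s])
            pos += s

    out._backward = bw
    return out


def upsample_nearest(x, factor=2):
    x = _as_tensor(x)
    f = int(factor)
    d = x.data
    up = np.repeat(np.repeat(np.repeat(d, f, axis=1), f, axis=2), f, axis=3)
    out = Tensor(up, parents=(x,))

    def bw(g):
        if x.requires_grad:
            C, X, Y, Z = x.shape
            gg = g.reshape(C, X, f, Y, f, Z, f).sum(axis=(2, 4, 6))
            x._accumulate(gg)

    out._backward = bw
    return out


def dropout(x, p, rng, training):
    if not training or p <= 0:
        return x
    x = _as_tensor(x)
    # channel-wise mask (spatial dropout), the usual choice for conv features
    mask = (rng.random(size=(x.shape[0],) + (1,) * (x.data.ndim - 1)) >= p) / (1.0 - p)
    mask = mask.astype(x.data.dtype)
    out = Tensor(x.data * mask, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# instance normalization
# ---------------------------------------------------------------------------

def instance_norm(x, gamma, beta, eps=1e-5):
    """Per-channel normalization over the spatial axes (batch of one)."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = tuple(range(1, x.data.ndim))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (x.shape[0],) + (1,) * (x.data.ndim - 1)
    out = Tensor(gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape),
                 parents=(x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gy = g * gamma.data.reshape(gshape)
            m1 = gy.mean(axis=axes, keepdims=True)
            m2 = (gy * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(inv * (gy - m1 - xhat * m2))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# 3-D convolution
# ---------------------------------------------------------------------------

def _flat_offsets(k: int, yp: int, zp: int):
    return [(i, j, l, i * yp * zp + j * zp + l)
            for i in range(k) for j in range(k) for l in range(k)]


def _conv_flat(xp: np.ndarray, w: np.ndarray):
    """Stride-1 correlation on an already-padded input via flat views.

    Kernel taps become constant offsets in the flattened padded volume, so
    every GEMM operand is a view — no per-tap copies.  Positions whose taps
    would wrap rows land in the padded border and are cropped afterwards.
    """
    C, Xp, Yp, Zp = xp.shape
    k = w.shape[-1]
    F = w.shape[0]
    np_flat = Xp * Yp * Zp
    maxoff = (k - 1) * (Yp * Zp + Zp + 1)
    m = np_flat - maxoff
    x2 = xp.reshape(C, np_flat)
    y_acc = np.zeros((F, m), dtype=xp.dtype)
    for i, j, l, off in _flat_offsets(k, Yp, Zp):
        y_acc += w[:, :, i, j, l] @ x2[:, off : off + m]
    y_full = np.zeros((F, np_flat), dtype=xp.dtype)
    y_full[:, :m] = y_acc
    out = (Xp - k + 1, Yp - k + 1, Zp - k + 1)
    return np.ascontiguousarray(
        y_full.reshape(F, Xp, Yp, Zp)[:, : out[0], : out[1], : out[2]]
    )


def _conv_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    """Forward correlation; x (C,X,Y,Z), w (F,C,k,k,k) -> (y, padded input)."""
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3) if pad > 0 else x
    if stride == 1:
        return _conv_flat(xp, w), xp
    out_shape = tuple((s - k) // stride + 1 for s in xp.shape[1:])
    n = int(np.prod(out_shape))
    y = np.zeros((w.shape[0], n), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                sub = xp[
                    :,
                    i : i + 1 + stride * (out_shape[0] - 1) : stride,
                    j : j + 1 + stride * (out_shape[1] - 1) : stride,
                    l : l + 1 + stride * (out_shape[2] - 1) : stride,
                ].reshape(xp.shape[0], n)
                y += w[:, :, i, j, l] @ sub
    return y.reshape((w.shape[0],) + out_shape), xp


def conv3d(x, weight, bias=None, stride=1, padding=1):
    """3-D correlation with 'same'-style padding; stride 1 or 2.

    ``weight``: (F, C, k, k, k); ``bias``: (F,) or None.
    """
    x = _as_tensor(x)
    weight = _as_tensor(weight)
    bias_t = _as_tensor(bias) if bias is not None else None
    k = weight.data.shape[-1]
    in_shape = x.data.shape
    y, xp = _conv_raw(x.data, weight.data, stride, padding)
    if bias_t is not None:
        y = y + bias_t.data.reshape(-1, 1, 1, 1)
    parents = (x, weight) + ((bias_t,) if bias_t is not None else ())
    out = Tensor(y, parents=parents)

    def bw(g):
        F = weight.data.shape[0]
        g_mat = g.reshape(F, -1)  # (F, N)
        if bias_t is not None and bias_t.requires_grad:
            bias_t._accumulate(g_mat.sum(axis=1))
        if stride == 1:
            C, Xp, Yp, Zp = xp.shape
            np_flat = Xp * Yp * Zp
            m = np_flat - (k - 1) * (Yp * Zp + Zp + 1)
            g_full = np.zeros((F, Xp, Yp, Zp), dtype=g.dtype)
            gx, gy, gz = g.shape[1:]
            g_full[:, :gx, :gy, :gz] = g
            g2 = g_full.reshape(F, np_flat)
            x2 = xp.reshape(C, np_flat)
            if weight.requires_grad:
                dW = np.empty_like(weight.data)
                for i, j, l, off in _flat_offsets(k, Yp, Zp):
                    dW[:, :, i, j, l] = g2[:, :m] @ x2[:, off : off + m].T
                weight._accumulate(dW)
            if x.requires_grad:
                dxp = np.zeros((C, np_flat), dtype=g.dtype)
                gv = g2[:, :m]
                for i, j, l, off in _flat_offsets(k, Yp, Zp):
                    dxp[:, off : off + m] += weight.data[:, :, i, j, l].T @ gv
                dx3 = dxp.reshape(C, Xp, Yp, Zp)
                if padding > 0:
                    dx3 = dx3[:, padding:Xp - padding, padding:Yp - padding,
                              padding:Zp - padding]
                x._accumulate(np.ascontiguousarray(dx3))
            return
        if weight.requires_grad:
            out_shape = g.shape[1:]
            n = g_mat.shape[1]
            dW = np.empty_like(weight.data)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        sub = xp[
                            :,
                            i : i + 1 + stride * (out_shape[0] - 1) : stride,
                            j : j + 1 + stride * (out_shape[1] - 1) : stride,
                            l : l + 1 + stride * (out_shape[2] - 1) : stride,
                        ].reshape(xp.shape[0], n)
                        dW[:, :, i, j, l] = g_mat @ sub.T
            weight._accumulate(dW)
        if x.requires_grad:
            # full convolution of the zero-stuffed output gradient with the
            # flipped kernel, asymmetric padding undoing the stride floor
            gd = np.zeros((F,) + tuple((s - 1) * stride + 1 for s in g.shape[1:]),
                          dtype=g.dtype)
            gd[:, ::stride, ::stride, ::stride] = g
            pad_lo = k - 1 - padding
            pads = []
            for ax in range(3):
                missing = (in_shape[1 + ax] + 2 * padding - k) % stride
                pads.append((pad_lo, pad_lo + missing))
            gdp = np.pad(gd, ((0, 0),) + tuple(pads))
            w_flip = weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            dx, _ = _conv_raw(gdp, np.ascontiguousarray(w_flip), 1, 0)
            x._accumulate(dx)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# finite-difference gradient check (used by the test suite)
# ---------------------------------------------------------------------------

def numeric_gradient(fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar ``fn`` w.r.t. ``x``."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (fn(xp) - fn(xm)) / (2 * eps)
        it.iternext()
    return g
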