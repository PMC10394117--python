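"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape: every operation returns a :class:`Tensor` holding the result
and closures that map the upstream gradient to contributions for each
parent.  Only the primitives needed by the registration networks are
implemented (elementwise arithmetic, matmul, reductions, 2-D/3-D strided
convolution, batch normalization, nearest up-sampling, concatenation,
bilinear map sampling).  Everything runs in float64; gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter",
    "add", "sub", "mul", "neg", "matmul", "reshape", "concat",
    "sum_all", "mean_all", "relu", "leaky_relu",
    "conv2d", "conv3d", "batchnorm", "upsample_nearest",
    "bilinear_sample", "stack_last",
]


class Tensor:
    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)       # tuples (Tensor, grad_fn)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in parents
        )

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    # -- backward ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t.parents:               # leaf: accumulate into .grad
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, fn in t.parents:
                if not p.requires_grad:
                    continue
                contrib = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                elif not p.parents:
                    p.grad = contrib if p.grad is None else p.grad + contrib
                else:
                    grads[id(p)] = contrib
        # note: leaves accumulate directly so diamond graphs still sum


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def constant(x) -> Tensor:
    return _as_tensor(x)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def _unbroadcast(grad, shape):
    """Reduce a broadcasted gradient back to ``shape``."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data,
                  [(a, lambda g: _unbroadcast(g, a.data.shape)),
                   (b, lambda g: _unbroadcast(g, b.data.shape))])


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data - b.data,
                  [(a, lambda g: _unbroadcast(g, a.data.shape)),
                   (b, lambda g: _unbroadcast(-g, b.data.shape))])


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, [(a, lambda g: -g)])


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data * b.data,
                  [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
                   (b, lambda g: _unbroadcast(g * a.data, b.data.shape))])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data @ b.data,
                  [(a, lambda g: g @ np.swapaxes(b.data, -1, -2)),
                   (b, lambda g: np.swapaxes(a.data, -1, -2) @ g)])


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return Tensor(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        sl = [slice(None)] * tensors[i].data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        return lambda g: g[tuple(sl)]

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  [(t, make_fn(i)) for i, t in enumerate(tensors)])


def stack_last(tensors) -> Tensor:
    """Stack equal-shape tensors along a new trailing axis."""
    tensors = [_as_tensor(t) for t in tensors]

    def make_fn(i):
        return lambda g: g[..., i]

    return Tensor(np.stack([t.data for t in tensors], axis=-1),
                  [(t, make_fn(i)) for i, t in enumerate(tensors)])


def sum_all(a: Tensor) -> Tensor:
    return Tensor(a.data.sum(), [(a, lambda g: np.broadcast_to(g, a.data.shape).copy())])


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size
    return Tensor(a.data.mean(),
                  [(a, lambda g: np.broadcast_to(g / n, a.data.shape).copy())])


def relu(a: Tensor) -> Tensor:
    m = a.data > 0
    return Tensor(a.data * m, [(a, lambda g: g * m)])


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    f = np.where(a.data > 0, 1.0, slope)
    return Tensor(a.data * f, [(a, lambda g: g * f)])


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """Strided 2-D correlation, NCHW layout, zero padding."""
    B, C, H, W = x.data.shape
    O, Ci, kh, kw = w.data.shape
    assert Ci == C, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    out = np.zeros((B, O, Ho, Wo))
    for di in range(kh):
        for dj in range(kw):
            xs = xp[:, :, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride]
            out += np.tensordot(xs, w.data[:, :, di, dj],
                                axes=([1], [1])).transpose(0, 3, 1, 2)
    out += b.data[None, :, None, None]

    def grad_x(g):
        gxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                gs = np.tensordot(g, w.data[:, :, di, dj],
                                  axes=([1], [0])).transpose(0, 3, 1, 2)
                gxp[:, :, di:di + stride * Ho:stride,
                    dj:dj + stride * Wo:stride] += gs
        return gxp[:, :, pad:pad + H, pad:pad + W] if pad else gxp

    def grad_w(g):
        gw = np.zeros_like(w.data)
        for di in range(kh):
            for dj in range(kw):
                xs = xp[:, :, di:di + stride * Ho:stride,
                        dj:dj + stride * Wo:stride]
                gw[:, :, di, dj] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
        return gw

    return Tensor(out, [(x, grad_x), (w, grad_w),
                        (b, lambda g: g.sum(axis=(0, 2, 3)))])


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """Strided 3-D correlation, NCDHW layout, zero padding."""
    B, C, D, H, W = x.data.shape
    O, Ci, kd, kh, kw = w.data.shape
    assert Ci == C, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Do = (D + 2 * pad - kd) // stride + 1
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    out = np.zeros((B, O, Do, Ho, Wo))
    for dk in range(kd):
        for di in range(kh):
            for dj in range(kw):
                xs = xp[:, :, dk:dk + stride * Do:stride,
                        di:di + stride * Ho:stride, dj:dj + stride * Wo:stride]
                out += np.tensordot(xs, w.data[:, :, dk, di, dj],
                                    axes=([1], [1])).transpose(0, 4, 1, 2, 3)
    out += b.data[None, :, None, None, None]

    def grad_x(g):
        gxp = np.zeros_like(xp)
        for dk in range(kd):
            for di in range(kh):
                for dj in range(kw):
                    gs = np.tensordot(g, w.data[:, :, dk, di, dj],
                                      axes=([1], [0])).transpose(0, 4, 1, 2, 3)
                    gxp[:, :, dk:dk + stride * Do:stride,
                        di:di + stride * Ho:stride,
                        dj:dj + stride * Wo:stride] += gs
        if pad:
            return gxp[:, :, pad:pad + D, pad:pad + H, pad:pad + W]
        return gxp

    def grad_w(g):
        gw = np.zeros_like(w.data)
        for dk in range(kd):
            for di in range(kh):
                for dj in range(kw):
                    xs = xp[:, :, dk:dk + stride * Do:stride,
                            di:di + stride * Ho:stride,
                            dj:dj + stride * Wo:stride]
                    gw[:, :, dk, di, dj] = np.tensordot(
                        g, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        return gw

    return Tensor(out, [(x, grad_x), (w, grad_w),
                        (b, lambda g: g.sum(axis=(0, 2, 3, 4)))])


# ---------------------------------------------------------------------------
# normalization, resampling
# ---------------------------------------------------------------------------

def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
              training: bool, momentum: float = 0.1, eps: float = 1e-5):
    """Batch normalization over all axes but channel (axis 1).

    Updates ``running_mean`` / ``running_var`` in place during training and
    returns the normalized tensor.
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    bshape = (1, -1) + (1,) * (x.data.ndim - 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size // x.data.shape[1]
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * n / max(n - 1, 1)
        std = np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(bshape)) / std.reshape(bshape)
        out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

        def grad_x(g):
            gxhat = g * gamma.data.reshape(bshape)
            m1 = gxhat.mean(axis=axes).reshape(bshape)
            m2 = (gxhat * xhat).mean(axis=axes).reshape(bshape)
            return (gxhat - m1 - xhat * m2) / std.reshape(bshape)

        return Tensor(out, [(x, grad_x),
                            (gamma, lambda g: (g * xhat).sum(axis=axes)),
                            (beta, lambda g: g.sum(axes))])
    std = np.sqrt(running_var + eps)
    xhat = (x.data - running_mean.reshape(bshape)) / std.reshape(bshape)
    out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)
    return Tensor(out, [(x, lambda g: g * (gamma.data / std).reshape(bshape)),
                        (gamma, lambda g: (g * xhat).sum(axis=axes)),
                        (beta, lambda g: g.sum(axes))])


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbor upsampling of every spatial axis (NC[D]HW layout)."""
    sp = x.data.ndim - 2
    out = x.data
    for ax in range(2, 2 + sp):
        out = np.repeat(out, factor, axis=ax)

    def grad(g):
        for ax in range(2, 2 + sp):
            shape = list(g.shape)
            shape[ax] //= factor
            shape.insert(ax + 1, factor)
            g = g.reshape(shape).sum(axis=ax + 1)
        return g

    return Tensor(out, [(x, grad)])


def bilinear_sample(fm: Tensor, rowcol: np.ndarray, mask: np.ndarray = None) -> Tensor:
    """Bilinear sampling of a (C, H, W) feature map at N fractional
    (row, col) locations; rows with ``mask == False`` yield zero features.

    Gradients flow into the feature map only (sampling locations are inputs,
    not parameters).
    """
    C, H, W = fm.data.shape
    pts = np.asarray(rowcol, dtype=np.float64)
    N = pts.shape[0]
    if mask is None:
        mask = np.ones(N, dtype=bool)
    r = np.clip(pts[:, 0], 0.0, H - 1.0)
    c = np.clip(pts[:, 1], 0.0, W - 1.0)
    r0 = np.clip(np.floor(r).astype(int), 0, H - 2) if H > 1 else np.zeros(N, int)
    c0 = np.clip(np.floor(c).astype(int), 0, W - 2) if W > 1 else np.zeros(N, int)
    fr = r - r0
    fc = c - c0
    w00 = (1 - fr) * (1 - fc)
    w01 = (1 - fr) * fc
    w10 = fr * (1 - fc)
    w11 = fr * fc
    m = mask.astype(np.float64)
    out = (w00[:, None] * fm.data[:, r0, c0].T
           + w01[:, None] * fm.data[:, r0, c0 + 1].T
           + w10[:, None] * fm.data[:, r0 + 1, c0].T
           + w11[:, None] * fm.data[:, r0 + 1, c0 + 1].T) * m[:, None]

    def grad(g):
        gm = g * m[:, None]                  # (N, C)
        gfm = np.zeros_like(fm.data)
        for w, dr, dc in ((w00, 0, 0), (w01, 0, 1), (w10, 1, 0), (w11, 1, 1)):
            np.add.at(gfm, (slice(None), r0 + dr, c0 + dc), (gm * w[:, None]).T)
        return gfm

    return Tensor(out, [(fm, grad)])
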