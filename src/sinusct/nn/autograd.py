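"""Minimal reverse-mode automatic differentiation on numpy ndarrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients into every node with ``requires_grad``.  Only the
operations needed by the volumetric networks in this package are provided
(elementwise arithmetic, batched matmul, reductions, reshaping, padding,
rolling, softmax, 3D convolution / transposed convolution / max-pooling and
the fused normalisation layers).

Everything is float32 and CPU-only; heavy lifting is delegated to BLAS via
``matmul``/``einsum`` with an im2col layout for convolutions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "conv_transpose3d",
    "maxpool3d",
    "group_norm",
    "layer_norm",
    "softmax",
    "dropout",
    "no_grad",
]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _NoGrad:
    _depth = 0

    def __enter__(self):
        _NoGrad._depth += 1
        return self

    def __exit__(self, *exc):
        _NoGrad._depth -= 1
        return False

    @staticmethod
    def active() -> bool:
        return _NoGrad._depth > 0


def no_grad() -> _NoGrad:
    """Context manager disabling tape recording (inference mode)."""
    return _NoGrad()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad.active()
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction of derived nodes ------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward):
        req = any(p.requires_grad for p in parents) and not _NoGrad.active()
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            a._accum(g * sign)

        return Tensor._make(np.abs(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        a = self
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = a.data
        t = np.tanh(c * (x + 0.044715 * x ** 3))
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x ** 2)
            a._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._make(out_data.astype(np.float32), (a,), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).astype(np.float32))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation --------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def backward(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(np.transpose(g, inv))

        return Tensor._make(np.ascontiguousarray(np.transpose(a.data, axes)), (a,), backward)

    def pad(self, pad_width):
        """Constant zero-padding; ``pad_width`` as for :func:`numpy.pad`."""
        a = self
        pw = tuple(tuple(p) for p in pad_width)

        def backward(g):
            sl = tuple(slice(lo, g.shape[i] - hi) for i, (lo, hi) in enumerate(pw))
            a._accum(g[sl])

        return Tensor._make(np.pad(a.data, pw), (a,), backward)

    def __getitem__(self, idx):
        a = self
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice)) for i in idx))

        def backward(g):
            buf = np.zeros_like(a.data)
            if basic:
                buf[idx] += g
            else:
                np.add.at(buf, idx, g)
            a._accum(buf)

        return Tensor._make(a.data[idx], (a,), backward)

    def roll(self, shift, axis):
        a = self
        shift = tuple(shift) if isinstance(shift, (tuple, list)) else (shift,)
        axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)

        def backward(g):
            a._accum(np.roll(g, tuple(-s for s in shift), axis))

        return Tensor._make(np.roll(a.data, shift, axis), (a,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -------------------------------------------------------------------------
# free functions
# -------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = x
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        gy = g * out_data
        a._accum(gy - out_data * gy.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (a,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(np.float32) / np.float32(1.0 - p)
    return x * Tensor(keep)


# -- fused normalisations ---------------------------------------------------

def _norm_core(x: np.ndarray, axes: tuple[int, ...], eps: float):
    mu = x.mean(axis=axes, keepdims=True)
    var = x.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat.astype(np.float32), inv.astype(np.float32)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the trailing (channel) dimension."""
    axes = (-1,)
    xhat, inv = _norm_core(x.data, axes, eps)
    out_data = xhat * weight.data + bias.data
    n = x.data.shape[-1]

    def backward(g):
        if weight.requires_grad:
            red = tuple(range(g.ndim - 1))
            weight._accum((g * xhat).sum(axis=red))
            bias._accum(g.sum(axis=red))
        if x.requires_grad:
            gy = g * weight.data
            m1 = gy.mean(axis=axes, keepdims=True)
            m2 = (gy * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv * (gy - m1 - xhat * m2))

    return Tensor._make(out_data, (x, weight, bias), backward)


def group_norm(x: Tensor, num_groups: int, weight: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Group normalisation over (channel-group, spatial) for (N, C, ...) input."""
    N, C = x.data.shape[:2]
    spatial = x.data.shape[2:]
    G = num_groups
    if C % G:
        raise ValueError(f"channels {C} not divisible by {G} groups")
    xg = x.data.reshape(N, G, -1)
    xhat, inv = _norm_core(xg, (2,), eps)
    xhat_full = xhat.reshape(x.data.shape)
    wshape = (1, C) + (1,) * len(spatial)
    out_data = xhat_full * weight.data.reshape(wshape) + bias.data.reshape(wshape)

    def backward(g):
        if weight.requires_grad:
            red = (0,) + tuple(range(2, g.ndim))
            weight._accum((g * xhat_full).sum(axis=red))
            bias._accum(g.sum(axis=red))
        if x.requires_grad:
            gy = (g * weight.data.reshape(wshape)).reshape(N, G, -1)
            m1 = gy.mean(axis=2, keepdims=True)
            m2 = (gy * xhat).mean(axis=2, keepdims=True)
            gx = inv * (gy - m1 - xhat * m2)
            x._accum(gx.reshape(x.data.shape))

    return Tensor._make(out_data, (x, weight, bias), backward)


# -- 3D convolution family --------------------------------------------------

def _im2col(xp: np.ndarray, k: tuple[int, int, int], s: int):
    """(N, C, X, Y, Z) padded input -> (N, O, C*kx*ky*kz) columns."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(xp, k, axis=(2, 3, 4))  # N,C,ox,oy,oz,kx,ky,kz
    win = win[:, :, ::s, ::s, ::s]
    N, C, ox, oy, oz = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(N, ox * oy * oz, -1)
    return np.ascontiguousarray(cols), (ox, oy, oz)


def _col2im(gcols: np.ndarray, xp_shape, k, s, out_sp):
    """Scatter-add column gradients back onto the padded input grid."""
    N, C = xp_shape[:2]
    ox, oy, oz = out_sp
    g = gcols.reshape(N, ox, oy, oz, C, k[0], k[1], k[2])
    gxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(k[0]):
        for j in range(k[1]):
            for l in range(k[2]):
                gxp[:, :, i:i + s * ox:s, j:j + s * oy:s, l:l + s * oz:s] += \
                    g[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
    return gxp


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """3D cross-correlation; x (N,Cin,X,Y,Z), w (Cout,Cin,kx,ky,kz)."""
    k = w.data.shape[2:]
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    cols, out_sp = _im2col(xp, k, stride)
    wmat = w.data.reshape(w.data.shape[0], -1)  # Cout x (Cin*kk)
    out = cols @ wmat.T  # N, O, Cout
    if b is not None:
        out += b.data
    N = x.data.shape[0]
    out_data = np.ascontiguousarray(
        out.transpose(0, 2, 1).reshape(N, w.data.shape[0], *out_sp))
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(N, g.shape[1], -1).transpose(0, 2, 1)  # N, O, Cout
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.einsum("nof,noc->cf", cols, gmat, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = gmat @ wmat  # N, O, Cin*kk
            gxp = _col2im(gcols, xp.shape, k, stride, out_sp)
            if p:
                gxp = gxp[:, :, p:-p, p:-p, p:-p]
            x._accum(gxp)

    return Tensor._make(out_data, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Transposed 3D convolution; x (N,Cin,...), w (Cin,Cout,k,k,k), no padding.

    Output spatial size is ``(in - 1) * stride + k`` per axis; with k == stride
    this is exact upsampling by the stride factor.
    """
    N, Cin, X, Y, Z = x.data.shape
    k = w.data.shape[2:]
    Co = w.data.shape[1]
    out_sp = tuple((n - 1) * stride + kk for n, kk in zip((X, Y, Z), k))
    out = np.zeros((N, Co, *out_sp), dtype=np.float32)
    xt = x.data.transpose(0, 2, 3, 4, 1)  # N,X,Y,Z,Cin
    for i in range(k[0]):
        for j in range(k[1]):
            for l in range(k[2]):
                contrib = xt @ w.data[:, :, i, j, l]  # N,X,Y,Z,Cout
                out[:, :, i:i + stride * X:stride, j:j + stride * Y:stride,
                    l:l + stride * Z:stride] += contrib.transpose(0, 4, 1, 2, 3)
    if b is not None:
        out += b.data.reshape(1, Co, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(k[0]):
            for j in range(k[1]):
                for l in range(k[2]):
                    gsl = g[:, :, i:i + stride * X:stride, j:j + stride * Y:stride,
                            l:l + stride * Z:stride].transpose(0, 2, 3, 4, 1)
                    if w.requires_grad:
                        gw = np.einsum("nxyzc,nxyzd->cd", xt, gsl, optimize=True)
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, i, j, l] += gw
                    if gx is not None:
                        gx += (gsl @ w.data[:, :, i, j, l].T).transpose(0, 4, 1, 2, 3)
        if gx is not None:
            x._accum(gx)

    return Tensor._make(out, parents, backward)


def maxpool3d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling with cubic kernel/stride ``k``."""
    N, C, X, Y, Z = x.data.shape
    if X % k or Y % k or Z % k:
        raise ValueError("maxpool3d requires spatial dims divisible by the kernel")
    xr = x.data.reshape(N, C, X // k, k, Y // k, k, Z // k, k)
    xw = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, X // k, Y // k, Z // k, k ** 3)
    arg = xw.argmax(axis=-1)
    out_data = np.take_along_axis(xw, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros(xw.shape, dtype=np.float32)
        np.put_along_axis(gw, arg[..., None], g[..., None], axis=-1)
        gw = gw.reshape(N, C, X // k, Y // k, Z // k, k, k, k)
        gx = gw.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, X, Y, Z)
        x._accum(np.ascontiguousarray(gx))

    return Tensor._make(np.ascontiguousarray(out_data), (x,), backward)
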