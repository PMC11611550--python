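"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core the attention blocks, generator, discriminator and
training loop are built on: a small define-by-run tape of :class:`Tensor`
nodes, each holding a NumPy array and a backward closure.  Only the primitives
the networks actually need are provided (elementwise arithmetic, matmul,
reductions, slicing/reshaping, 3D convolution via im2col, nearest-neighbour
upsampling).  Gradients are accumulated by a topological sweep in
:meth:`Tensor.backward`.

Convolutions keep the NCDHW layout throughout: arrays are
``(batch, channels, depth, height, width)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "upsample3d",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum surplus leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a NumPy array."""

    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._children: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _make(data, children, backward) -> "Tensor":
        out = Tensor(data)
        if any(c.requires_grad for c in children):
            out.requires_grad = True
            out._children = tuple(children)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for c in node._children:
                stack.append((c, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- info --------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def back(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def back(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def back(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), back)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), back)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = np.matmul(self.data, other.data)

        def back(out):
            g = out.grad
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * out.data)

        return Tensor._make(out_data, (self,), back)

    def log(self):
        out_data = np.log(self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return Tensor._make(out_data, (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))

        return Tensor._make(out_data, (self,), back)

    def sigmoid(self):
        out_data = expit(self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        return Tensor._make(out_data, (self,), back)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        return Tensor._make(out_data, (self,), back)

    def leaky_relu(self, slope: float = 0.2):
        out_data = np.where(self.data > 0, self.data, slope * self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, slope))

        return Tensor._make(out_data, (self,), back)

    def abs(self):
        out_data = np.abs(self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))

        return Tensor._make(out_data, (self,), back)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def back(out):
            if not self.requires_grad:
                return
            g, m = out.grad, out.data
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                m = np.expand_dims(m, axis)
            mask = (self.data == m).astype(self.data.dtype)
            # split gradient equally between tied maxima
            cnt = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accum(np.broadcast_to(g, self.data.shape) * mask / cnt)

        return Tensor._make(out_data, (self,), back)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        return Tensor._make(out_data, (self,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        return Tensor._make(out_data, (self,), back)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def back(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        return Tensor._make(out_data, (self,), back)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from engine primitives."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant w.r.t. grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# 3D convolution (im2col) and upsampling
# ---------------------------------------------------------------------------

def _triple(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


def _im2col(xp: np.ndarray, k, s, out_sp):
    """View padded NCDHW input as (N, C*kd*kh*kw, L) patch matrix."""
    n, c = xp.shape[:2]
    kd, kh, kw = k
    sd, sh, sw = s
    do, ho, wo = out_sp
    st = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kd, kh, kw, do, ho, wo),
        strides=(st[0], st[1], st[2], st[3], st[4], st[2] * sd, st[3] * sh, st[4] * sw),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(n, c * kd * kh * kw, do * ho * wo)


def _col2im(cols: np.ndarray, x_shape, k, s, pad, out_sp) -> np.ndarray:
    """Scatter-add patch matrix back onto the (unpadded) input grid."""
    n, c, d, h, w = x_shape
    kd, kh, kw = k
    sd, sh, sw = s
    pd, ph, pw = pad
    do, ho, wo = out_sp
    xp = np.zeros((n, c, d + 2 * pd, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    cols = cols.reshape(n, c, kd, kh, kw, do, ho, wo)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                xp[:, :, i : i + sd * do : sd, j : j + sh * ho : sh, l : l + sw * wo : sw] += cols[
                    :, :, i, j, l
                ]
    return xp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]


def _conv3d_fft(x: Tensor, w: Tensor, b: Tensor | None, p) -> Tensor:
    """Stride-1 convolution via FFT, used for large kernels with few channel
    pairs (the generator's big input convolution)."""
    from scipy.signal import fftconvolve

    n, c, d, h, wd = x.data.shape
    o = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    wf = w.data[:, :, ::-1, ::-1, ::-1]
    out_data = np.empty((n, o, d, h, wd), dtype=np.result_type(x.data, w.data))
    for ni in range(n):
        for oi in range(o):
            acc = fftconvolve(xp[ni, 0], wf[oi, 0], mode="valid")
            for ci in range(1, c):
                acc += fftconvolve(xp[ni, ci], wf[oi, ci], mode="valid")
            out_data[ni, oi] = acc
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)
    children = (x, w) if b is None else (x, w, b)

    def back(out):
        g = out.grad
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for ni in range(n):
                for oi in range(o):
                    gf = g[ni, oi][::-1, ::-1, ::-1]
                    for ci in range(c):
                        gw[oi, ci] += fftconvolve(xp[ni, ci], gf, mode="valid")
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(xp)
            for ni in range(n):
                for ci in range(c):
                    for oi in range(o):
                        gx[ni, ci] += fftconvolve(g[ni, oi], w.data[oi, ci], mode="full")
            x._accum(gx[:, :, p[0] : p[0] + d, p[1] : p[1] + h, p[2] : p[2] + wd])

    return Tensor._make(out_data, children, back)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0) -> Tensor:
    """3D cross-correlation, NCDHW input, (out_ch, in_ch, kd, kh, kw) weights."""
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    k = w.data.shape[2:]
    s = _triple(stride)
    p = _triple(padding)
    n, c, d, h, wd = x.data.shape
    o = w.data.shape[0]
    if (s == (1, 1, 1) and min(k) >= 5 and c * o <= 16
            and min(d, h, wd) >= 16 and k[0] == k[1] == k[2]
            and all(2 * pi == ki - 1 for pi, ki in zip(p, k))):
        return _conv3d_fft(x, w, b, p)
    out_sp = tuple((dim + 2 * pi - ki) // si + 1 for dim, pi, ki, si in zip((d, h, wd), p, k, s))
    if any(osz < 1 for osz in out_sp):
        raise ValueError(f"kernel {k} does not fit input {(d, h, wd)} with padding {p}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    cols = _im2col(xp, k, s, out_sp)
    wm = w.data.reshape(o, -1)
    out_data = np.matmul(wm, cols).reshape(n, o, *out_sp)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)

    children = (x, w) if b is None else (x, w, b)

    def back(out):
        g = out.grad.reshape(n, o, -1)
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wm.T, g)
            x._accum(_col2im(gcols, x.data.shape, k, s, p, out_sp))

    return Tensor._make(out_data, children, back)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=2, padding=1) -> Tensor:
    """Transposed 3D convolution (fractionally strided), NCDHW input,
    (in_ch, out_ch, kd, kh, kw) weights; out = (in-1)*s - 2p + k."""
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    k = w.data.shape[2:]
    s = _triple(stride)
    p = _triple(padding)
    n, c, d, h, wd = x.data.shape
    o = w.data.shape[1]
    in_sp = (d, h, wd)
    out_sp = tuple((dim - 1) * si - 2 * pi + ki for dim, si, pi, ki in zip(in_sp, s, p, k))
    if any(osz < 1 for osz in out_sp):
        raise ValueError(f"degenerate transposed-conv output {out_sp}")
    wm = w.data.reshape(c, -1)  # (c, o*k^3)
    xl = x.data.reshape(n, c, -1)
    cols = np.matmul(wm.T[None], xl)  # (n, o*k^3, L)
    out_data = _col2im(cols, (n, o, *out_sp), k, s, p, in_sp)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)
    children = (x, w) if b is None else (x, w, b)

    def back(out):
        g = out.grad
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        gp = np.pad(g, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
        cols_g = _im2col(gp, k, s, in_sp)  # (n, o*k^3, L)
        if w.requires_grad:
            gw = np.matmul(xl, cols_g.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gx = np.matmul(wm[None], cols_g)
            x._accum(gx.reshape(x.data.shape))

    return Tensor._make(out_data, children, back)


def upsample3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of each spatial axis by ``factor``."""
    f = int(factor)
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def back(out):
        if not x.requires_grad:
            return
        n, c, d, h, w = x.data.shape
        g = out.grad.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))
        x._accum(g)

    return Tensor._make(out_data, (x,), back)
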