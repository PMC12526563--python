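"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is a tape of coarse-grained array operations: each `Tensor` records
the closure that propagates its output gradient back to its parents.  Ops are
deliberately layer-sized (a whole convolution is one node) so that the Python
overhead per training step stays negligible next to the BLAS work.

Only what the lesion-segmentation models need is implemented: convolution
(via im2col), transposed convolution, batch/group normalisation, SiLU/sigmoid
/softmax, pooling, nearest & bilinear resampling, a spectral low-pass
(DFT crop) primitive, concatenation/slicing, fancy gather, and the usual
broadcasting arithmetic/reductions.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "SGD"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "decay", "_backward", "_parents")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self.decay = False
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

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
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free tape memory as we go
                node._backward = None

    # -- op construction helper ------------------------------------------

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward):
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data)
        if req:
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.shape))

        return Tensor._make(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accumulate(g * p * np.power(self.data, p - 1))

        return Tensor._make(np.power(self.data, p), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- activations ------------------------------------------------------

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out_data = self.data * s

        def backward(g):
            self._accumulate(g * (s + out_data * (1.0 - s)))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accumulate(p * (g - dot))

        return Tensor._make(p, (self,), backward)

    # -- reductions / reshapes -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        out_data = self.data.mean(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g) / n
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def matmul(self, other: "Tensor"):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)


# ---------------------------------------------------------------------------
# functional ops used by the layers
# ---------------------------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def chunk(t: Tensor, n: int, axis: int = 1) -> list[Tensor]:
    size = t.shape[axis] // n
    outs = []
    for i in range(n):
        sl = [slice(None)] * t.ndim
        sl[axis] = slice(i * size, (i + 1) * size)
        outs.append(t[tuple(sl)])
    return outs


def maximum(a: Tensor, b: Tensor) -> Tensor:
    mask = a.data >= b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~mask), b.shape))

    return Tensor._make(np.maximum(a.data, b.data), (a, b), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward)


# -- convolution -----------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    n, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (x.shape[2] - kh) // sh + 1
    wo = (x.shape[3] - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * sh, s3 * sw),
        writeable=False,
    )
    return np.ascontiguousarray(cols.reshape(n, c * kh * kw, ho * wo)), ho, wo


def _col2im(cols: np.ndarray, xshape, kh, kw, sh, sw, ph, pw, ho, wo):
    n, c, h, w = xshape
    hp, wp = h + 2 * ph, w + 2 * pw
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += cols[:, :, i, j]
    return out[:, :, ph : ph + h, pw : pw + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=(1, 1), padding=(0, 0)) -> Tensor:
    """2-D cross-correlation, NCHW, weight (Cout, Cin, Kh, Kw)."""
    sh, sw = stride
    ph, pw = padding
    co, ci, kh, kw = w.shape
    n = x.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    wmat = w.data.reshape(co, ci * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(n, co, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1, 1)

    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g):
        gmat = g.reshape(n, co, ho * wo)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            gx = _col2im(gcols, x.shape, kh, kw, sh, sw, ph, pw, ho, wo)
            x._accumulate(gx)

    return Tensor._make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2) -> Tensor:
    """Transposed conv with kernel == stride (non-overlapping upsampling).

    Weight layout (Cin, Cout, K, K).  This is the only flavour the prototype
    mask module needs.
    """
    ci, co, k, _ = w.shape
    n, _, h, wdt = x.shape
    assert k == stride, "only kernel==stride supported"
    # out[n, co, h*k + i, w*k + j] = sum_ci x[n, ci, h, w] * w[ci, co, i, j]
    out_data = np.einsum("nchw,cokl->nohkwl", x.data, w.data, optimize=True)
    out_data = out_data.reshape(n, co, h * k, wdt * k)
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g):
        gg = g.reshape(n, co, h, k, wdt, k)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("nohkwl,nchw->cokl", gg, x.data, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("nohkwl,cokl->nchw", gg, w.data, optimize=True))

    return Tensor._make(out_data, parents, backward)


# -- pooling / resampling --------------------------------------------------


def max_pool2d(x: Tensor, k: int, stride: int = 1, padding: int | None = None) -> Tensor:
    if padding is None:
        padding = k // 2
    n, c, h, w = x.shape
    neg = np.float32(-1e30)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, ho, wo, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3), writeable=False)
    flat = win.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros_like(xp)
        ii, jj = np.divmod(arg, k)
        ni, ci_, hi, wi = np.indices(arg.shape)
        rows = hi * stride + ii
        cols_ = wi * stride + jj
        np.add.at(gxp, (ni, ci_, rows, cols_), g)
        x._accumulate(gxp[:, :, padding : padding + h, padding : padding + w])

    return Tensor._make(np.ascontiguousarray(out_data), (x,), backward)


def _box_sum(a: np.ndarray, k: int, h: int, w: int) -> np.ndarray:
    """Sum over kxk windows centred on each pixel (edges see fewer pixels)."""
    p = k // 2
    ap = np.pad(a, ((0, 0), (0, 0), (p, p), (p, p)))
    cs = ap.cumsum(axis=2).cumsum(axis=3)
    cs = np.pad(cs, ((0, 0), (0, 0), (1, 0), (1, 0)))
    return (
        cs[:, :, k : k + h, k : k + w]
        - cs[:, :, :h, k : k + w]
        - cs[:, :, k : k + h, :w]
        + cs[:, :, :h, :w]
    )


def avg_pool2d_s1(x: Tensor, k: int) -> Tensor:
    """Stride-1 average pooling with same spatial size.

    Border windows are normalised by the number of in-image pixels they
    actually cover, so a constant map stays exactly constant.
    """
    n, c, h, w = x.shape
    count = _box_sum(np.ones((1, 1, h, w), np.float32), k, h, w)
    out_data = _box_sum(x.data, k, h, w) / count

    def backward(g):
        # out = D B x with D = diag(1/count); adjoint is B^T D g, and the
        # centred box sum is self-adjoint
        x._accumulate(_box_sum(g / count, k, h, w))

    return Tensor._make(out_data.astype(np.float32), (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


def _bilinear_weights(n_in: int, n_out: int):
    """align_corners=False sampling weights; returns (idx0, idx1, w1)."""
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    return i0, i1, (pos - i0).astype(np.float32)


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    h_out, w_out = out_hw
    n, c, h, w = x.shape
    if (h, w) == (h_out, w_out):
        return x
    r0, r1, rw = _bilinear_weights(h, h_out)
    c0, c1, cw = _bilinear_weights(w, w_out)
    rw_ = rw[:, None]
    cw_ = cw[None, :]
    d = x.data
    top = d[:, :, r0][:, :, :, c0] * (1 - cw_) + d[:, :, r0][:, :, :, c1] * cw_
    bot = d[:, :, r1][:, :, :, c0] * (1 - cw_) + d[:, :, r1][:, :, :, c1] * cw_
    out_data = top * (1 - rw_) + bot * rw_

    def backward(g):
        gx = np.zeros_like(x.data)
        for (ri, rwt) in ((r0, 1 - rw), (r1, rw)):
            for (cj, cwt) in ((c0, 1 - cw), (c1, cw)):
                contrib = g * rwt[:, None] * cwt[None, :]
                np.add.at(gx, (slice(None), slice(None), ri[:, None], cj[None, :]), contrib)
        x._accumulate(gx)

    return Tensor._make(out_data.astype(np.float32), (x,), backward)


# -- spectral low-pass -----------------------------------------------------


def spectral_lowpass(x: Tensor) -> Tensor:
    """Per-channel 2-D DFT -> keep the top-left (low-frequency) quadrant ->
    inverse DFT on the cropped grid, real part.

    Cropped size is (ceil(H/2), ceil(W/2)).  The inverse is scaled by 1/(H*W)
    so that a constant input maps to the same constant (only the DC bin
    survives the crop).  Linear in x; the backward pass is the adjoint map.
    """
    n, c, h, w = x.shape
    hc, wc = (h + 1) // 2, (w + 1) // 2
    spec = np.fft.fft2(x.data, axes=(-2, -1))[:, :, :hc, :wc]
    # unnormalised inverse on the cropped grid, then 1/(H*W)
    out = np.fft.ifft2(spec, axes=(-2, -1)) * (hc * wc / (h * w))
    out_data = out.real.astype(np.float32)

    def backward(g):
        # adjoint: E^T g (unnormalised IDFT of g), zero-pad, DFT, scale, Re
        gg = np.fft.ifft2(g, axes=(-2, -1)) * (hc * wc)
        pad = np.zeros((n, c, h, w), dtype=complex)
        pad[:, :, :hc, :wc] = gg
        gx = np.fft.fft2(pad, axes=(-2, -1)) / (h * w)
        x._accumulate(gx.real.astype(np.float32))

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------


class SGD:
    """SGD with classical momentum and decoupled weight decay.

    Weight decay is applied only to parameters flagged `decay=True`
    (conv/linear weights; never norm affine terms or biases).
    """

    def __init__(self, params: Iterable, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "decay", False):
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def state_dict(self):
        return {"vel": [v.copy() for v in self._vel]}

    def load_state_dict(self, state):
        self._vel = [v.copy() for v in state["vel"]]


class Adam:
    """Adam with decoupled weight decay (AdamW-style) on flagged params."""

    def __init__(self, params: Iterable, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        bc1 = 1.0 - self.b1**self._t
        bc2 = 1.0 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and getattr(p, "decay", False):
                upd = upd + self.weight_decay * p.data
            p.data -= self.lr * upd

    def state_dict(self):
        return {"m": [m.copy() for m in self._m], "v": [v.copy() for v in self._v],
                "t": self._t}

    def load_state_dict(self, state):
        self._m = [m.copy() for m in state["m"]]
        self._v = [v.copy() for v in state["v"]]
        self._t = state["t"]
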