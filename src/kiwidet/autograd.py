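"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float32 numpy
array together with a backward closure, and free functions build the tape.
Only the operations the detector actually needs are provided (dense and
depthwise convolution, max-pooling, batch/layer normalisation, matmul,
softmax, the real/imaginary parts of the 2-D DFT, elementwise arithmetic,
and a couple of gather/scatter primitives for sparse attention).

Everything is single-threaded numpy and bitwise deterministic for a fixed
sequence of operations, which the training-reproducibility tests rely on.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True

# pad value for max-pooling: behaves like -inf without creating NaNs in
# downstream arithmetic on untouched borders
_NEG = np.float32(-1e30)


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _asarray(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        if x.dtype != np.float32:
            return x.astype(np.float32)
        return x
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        """Result node; tracks gradient only if enabled and any parent does."""
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = _asarray(grad)
        # iterative topological order (graphs are deep: ~60 conv layers)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures/buffers eagerly

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True) if g.dtype != np.float32 else g.copy()
        else:
            self.grad += g

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        ad, bd = a.data, b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * bd, ad.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * ad, bd.shape))

        return Tensor._make(ad * bd, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        ad, bd = a.data, b.data
        out = ad / bd

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / bd, ad.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * ad / (bd * bd), bd.shape))

        return Tensor._make(out, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        a = self
        ad = a.data

        def bw(g):
            a._accum(g * p * np.power(ad, p - 1))

        return Tensor._make(np.power(ad, p), (a,), bw)

    def __getitem__(self, idx):
        a = self
        out = a.data[idx]

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(out, (a,), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    def sum(self, axis=None, keepdims=False):
        a = self
        shp = a.data.shape

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, shp).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, shp).astype(np.float32))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- unary nonlinearities ------------------------------------------------
    def exp(self):
        a = self
        out = np.exp(a.data)

        def bw(g):
            a._accum(g * out)

        return Tensor._make(out, (a,), bw)

    def log(self):
        a = self
        ad = a.data

        def bw(g):
            a._accum(g / ad)

        return Tensor._make(np.log(ad), (a,), bw)

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out)

        return Tensor._make(out, (a,), bw)

    def sigmoid(self):
        a = self
        out = _sigmoid(a.data)

        def bw(g):
            a._accum(g * out * (1.0 - out))

        return Tensor._make(out, (a,), bw)

    def silu(self):
        a = self
        s = _sigmoid(a.data)
        out = a.data * s

        def bw(g):
            a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

        return Tensor._make(out, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def atan(self):
        a = self
        ad = a.data

        def bw(g):
            a._accum(g / (1.0 + ad * ad))

        return Tensor._make(np.arctan(ad), (a,), bw)

    def clip_min(self, lo: float):
        a = self
        mask = a.data > lo

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(np.maximum(a.data, lo), (a,), bw)

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other):
        a, b = self, other
        ad, bd = a.data, b.data

        def bw(g):
            if a.requires_grad:
                ga = g @ bd.swapaxes(-1, -2)
                a._accum(_unbroadcast(ga, ad.shape))
            if b.requires_grad:
                gb = ad.swapaxes(-1, -2) @ g
                b._accum(_unbroadcast(gb, bd.shape))

        return Tensor._make(ad @ bd, (a, b), bw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


# ---------------------------------------------------------------------------
# n-ary ops
# ---------------------------------------------------------------------------

def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    mask = a.data <= b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~mask), b.data.shape))

    return Tensor._make(np.minimum(a.data, b.data), (a, b), bw)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    mask = a.data >= b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~mask), b.data.shape))

    return Tensor._make(np.maximum(a.data, b.data), (a, b), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accum((g - dot) * out)

    return Tensor._make(out, (x,), bw)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, ph: int, pw: int, value: float = 0.0) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                  constant_values=np.float32(value))


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> view (N,C,Ho,Wo,kh,kw)."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """Dense 2-D convolution (cross-correlation), NCHW / (co,ci,kh,kw)."""
    N, C, H, W = x.data.shape
    co, ci, kh, kw = w.data.shape
    xp = _pad_hw(x.data, padding, padding)
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    cols = _windows(xp, kh, kw, stride, stride)            # N,C,Ho,Wo,kh,kw
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    cols = np.ascontiguousarray(cols)
    wm = w.data.reshape(co, ci * kh * kw)
    out = cols @ wm.T                                      # (N*Ho*Wo, co)
    if b is not None:
        out += b.data
    out = out.reshape(N, Ho, Wo, co).transpose(0, 3, 1, 2)

    def bw(g):
        gm = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, co)
        if w.requires_grad:
            w._accum((gm.T @ cols).reshape(co, ci, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            dcols = gm @ wm                                # (N*Ho*Wo, C*kh*kw)
            dcols = dcols.reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accum(dxp)

    return Tensor._make(out, tuple(t for t in (x, w, b) if t is not None), bw)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
                     padding: int = 0) -> Tensor:
    """Depthwise conv: one (kh,kw) kernel per channel; w shape (C,kh,kw)."""
    N, C, H, W = x.data.shape
    _, kh, kw = w.data.shape
    xp = _pad_hw(x.data, padding, padding)
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    v = _windows(xp, kh, kw, stride, stride)               # N,C,Ho,Wo,kh,kw
    out = np.einsum("nchwij,cij->nchw", v, w.data, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("nchw,nchwij->cij", g, v, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        g * w.data[None, :, i, j, None, None]
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accum(dxp)

    return Tensor._make(out, tuple(t for t in (x, w, b) if t is not None), bw)


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max-pooling; borders are padded with an effectively -inf value so
    padded entries never win (true neighbourhood maxima at the border)."""
    N, C, H, W = x.data.shape
    xp = _pad_hw(x.data, padding, padding, value=_NEG)
    Ho = (xp.shape[2] - kernel) // stride + 1
    Wo = (xp.shape[3] - kernel) // stride + 1
    v = _windows(xp, kernel, kernel, stride, stride).reshape(N, C, Ho, Wo, kernel * kernel)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros_like(xp)
        for f in range(kernel * kernel):
            i, j = divmod(f, kernel)
            mask = idx == f
            if mask.any():
                dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += g * mask
        if padding:
            dxp = dxp[:, :, padding:padding + H, padding:padding + W]
        x._accum(dxp)

    return Tensor._make(np.ascontiguousarray(out), (x,), bw)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    N, C, H, W = x.data.shape

    def bw(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                running_var: np.ndarray, training: bool, momentum: float = 0.03,
                eps: float = 1e-3) -> Tensor:
    """BatchNorm over (N,H,W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3), dtype=np.float64)
        var = x.data.var(axis=(0, 2, 3), dtype=np.float64)
        # population (biased) variance is stored so that recalibrated
        # statistics reproduce training-mode normalisation exactly
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
        mu = mu.astype(np.float32)
        ivar = (1.0 / np.sqrt(var + eps)).astype(np.float32)
        xhat = (x.data - mu[None, :, None, None]) * ivar[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gh = g * gamma.data[None, :, None, None]
                m1 = gh.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (gh * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accum((gh - m1 - xhat * m2) * ivar[None, :, None, None])

        return Tensor._make(out, (x, gamma, beta), bw)

    ivar = (1.0 / np.sqrt(running_var + eps)).astype(np.float32)
    mu = running_mean.astype(np.float32)
    xhat = (x.data - mu[None, :, None, None]) * ivar[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(g * (gamma.data * ivar)[None, :, None, None])

    return Tensor._make(out, (x, gamma, beta), bw)


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """LayerNorm over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    out = gamma.data * xhat + beta.data

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=-1, keepdims=True)
            m2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accum((gh - m1 - xhat * m2) * ivar)

    return Tensor._make(out, (x, gamma, beta), bw)


# ---------------------------------------------------------------------------
# frequency-domain ops
# ---------------------------------------------------------------------------

def fft2_real(x: Tensor) -> Tensor:
    """Real part of the unnormalised 2-D DFT over the two trailing axes.

    The map x -> Re(DFT2(x)) is linear with a symmetric matrix (the cosine
    kernel cos(2pi(un/H+vm/W)) is invariant under swapping (u,v)<->(n,m)),
    so its adjoint is itself: grad_x = Re(DFT2(grad_y)).
    """
    out = np.fft.fft2(x.data, axes=(-2, -1)).real.astype(np.float32)

    def bw(g):
        x._accum(np.fft.fft2(g, axes=(-2, -1)).real.astype(np.float32))

    return Tensor._make(out, (x,), bw)


def fft2_imag(x: Tensor) -> Tensor:
    """Imaginary part of the unnormalised 2-D DFT (self-adjoint, as above)."""
    out = np.fft.fft2(x.data, axes=(-2, -1)).imag.astype(np.float32)

    def bw(g):
        x._accum(np.fft.fft2(g, axes=(-2, -1)).imag.astype(np.float32))

    return Tensor._make(out, (x,), bw)


# ---------------------------------------------------------------------------
# gather/scatter primitives
# ---------------------------------------------------------------------------

def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of a 2-D tensor; backward scatter-adds."""
    out = x.data[idx]

    def bw(g):
        dx = np.zeros_like(x.data)
        np.add.at(dx, idx, g)
        x._accum(dx)

    return Tensor._make(out, (x,), bw)


def gather_regions(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather routed regions for bi-level routing attention.

    x: (N, R, T, d) per-region tokens; idx: (N, R, k) region ids.
    Returns (N, R, k, T, d).
    """
    N = x.data.shape[0]
    bi = np.arange(N)[:, None, None]
    out = x.data[bi, idx]

    def bw(g):
        dx = np.zeros_like(x.data)
        np.add.at(dx, (bi, idx), g)
        x._accum(dx)

    return Tensor._make(out, (x,), bw)


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    pos_weight: float | None = None) -> Tensor:
    """Numerically stable elementwise binary cross-entropy on logits.

    Returns the elementwise loss tensor (caller reduces).
    """
    z = logits.data
    t = target
    # log(1+exp(-|z|)) formulation
    log1p = np.log1p(np.exp(-np.abs(z)))
    loss = np.maximum(z, 0) - z * t + log1p
    s = _sigmoid(z)
    if pos_weight is not None:
        wmask = np.where(t > 0, pos_weight, 1.0).astype(np.float32)
        loss = loss * wmask

        def bw(g):
            logits._accum(g * wmask * (s - t))
    else:
        def bw(g):
            logits._accum(g * (s - t))

    return Tensor._make(loss.astype(np.float32), (logits,), bw)
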