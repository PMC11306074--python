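"""Frequency Domain Feature Fusion (FDFF).

The block converts a spatial feature map to the frequency domain with an
unnormalised 2-D DFT, keeps the real (amplitude-bearing) component, extracts
dominant frequency responses with a shape-preserving max-pool, multiplies
them back into the spatial features, and fuses the concatenated
spatial+frequency stack with a separable convolution followed by spatial
attention. High-frequency content corresponds to rapid grey-level change -
edges and contours - which is exactly what separates the four
pollination-stage flower classes (bud discs vs. petal rosettes vs. shed
petals) when colour cues are weak.

Functional primitives (numpy in / numpy out, used by the oracle tests) live
alongside the trainable :class:`FDFF` module, which wires the same pipeline
through the autograd engine.

Parameter bookkeeping of the default block at 64 input channels:

====================================  =======
1x1 expand  2C -> h (no bias)          16,128
3x3 depthwise on h (no bias)            1,134
1x1 project h -> C (bias)               8,128
BatchNorm(C)                              128
spatial attn 7x7 conv (no bias)+BN(1)     100
total                                  25,618
====================================  =======

with h = 2C - 2 = 126, the expansion width calibrated so that inserting the
block after the P3 stage of the nano detector reproduces the published
model total exactly (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from . import nn

SPECTRUM_MODES = ("real_only", "imag_only", "real_and_imag")


def _check_featuremap(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"feature map must be rank-4 (N,C,H,W), got rank {x.ndim}")
    if not np.isfinite(x).all():
        raise ValueError("feature map contains non-finite values")
    return x


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def fft2d(x: np.ndarray) -> np.ndarray:
    """Unnormalised forward 2-D DFT over the two spatial axes.

    Applied independently to every (batch, channel) slice; the output has
    the same extents as the input and is complex. The transform is lossless:
    ``ifft2d(fft2d(x))`` reconstructs ``x``.
    """
    x = _check_featuremap(x)
    return np.fft.fft2(x, axes=(-2, -1))


def ifft2d(s: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2d` (1/(H*W)-normalised), returning the real part."""
    return np.fft.ifft2(s, axes=(-2, -1)).real


def spectrum_to_real(s: np.ndarray, mode: str = "real_only") -> np.ndarray:
    """Project a complex spectrum onto a real feature map.

    ``real_only`` keeps the amplitude-bearing real component (the default the
    detector uses), ``imag_only`` the phase-bearing imaginary component, and
    ``real_and_imag`` stacks both along the channel axis (doubling C).
    """
    if mode not in SPECTRUM_MODES:
        raise ValueError(f"unknown spectrum mode {mode!r}; choose from {SPECTRUM_MODES}")
    if mode == "real_only":
        return s.real.copy()
    if mode == "imag_only":
        return s.imag.copy()
    return np.concatenate([s.real, s.imag], axis=1)


def freq_maxpool(xf: np.ndarray, kernel: int = 3, stride: int = 1) -> np.ndarray:
    """Max-filter in the frequency domain.

    Borders are padded with -inf surrogates so border outputs are true
    neighbourhood maxima; with the default kernel 3 / stride 1 the spatial
    extents are preserved, which the multiplicative fusion requires.
    """
    if kernel % 2 != 1:
        raise ValueError("pooling kernel must be odd")
    xf = np.asarray(xf, dtype=np.float32)
    t = ag.maxpool2d(Tensor(xf), kernel, stride, kernel // 2)
    return t.data


def fuse_multiply(xm: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Elementwise (Hadamard) frequency-spatial fusion X_MS = X_M * X_S."""
    xm, xs = np.asarray(xm), np.asarray(xs)
    if xm.shape != xs.shape:
        raise ValueError(f"shape mismatch: {xm.shape} vs {xs.shape}")
    return xm * xs


def conv_param_count(wf: int, hf: int, c_in: int, c_out: int) -> int:
    """Weight count of a dense convolution: WF*HF*CI*CO."""
    _check_pos(wf, hf, c_in, c_out)
    return wf * hf * c_in * c_out


def dsc_param_count(wf: int, hf: int, c_in: int, c_out: int) -> int:
    """Weight count of a depthwise-separable convolution:
    WF*HF*CI (depthwise) + 1*1*CI*CO (pointwise)."""
    _check_pos(wf, hf, c_in, c_out)
    return wf * hf * c_in + c_in * c_out


def _check_pos(*vals):
    for v in vals:
        if v < 1:
            raise ValueError("convolution dimensions must be >= 1")


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------

class DSC(nn.Module):
    """Standard depthwise-separable convolution.

    Depthwise k x k (one kernel per input channel, no bias) followed by a
    1x1 pointwise projection (bias) and batch normalisation.
    """

    def __init__(self, c1: int, c_out: int, kernel: int = 3, rng=None):
        if c_out < 1:
            raise ValueError("c_out must be >= 1")
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.dw = nn.Conv2d(c1, c1, kernel, bias=False, depthwise=True, rng=rng)
        self.pw = nn.Conv2d(c1, c_out, 1, bias=True, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.pw(self.dw(x)))


class SpatialAttention(nn.Module):
    """CBAM-style spatial gate.

    Channelwise max and mean are stacked into a 2-channel descriptor,
    convolved to a single channel (k x k, no bias, BN) and squashed by a
    sigmoid, yielding a per-pixel weight in (0, 1).
    """

    def __init__(self, kernel: int = 7, rng=None):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.conv = nn.Conv2d(2, 1, kernel, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(1)

    def forward(self, x: Tensor) -> Tensor:
        desc = channel_max_mean(x)
        return self.bn(self.conv(desc)).sigmoid()


def channel_max_mean(x: Tensor) -> Tensor:
    """Per-pixel (max over C, mean over C) 2-channel descriptor."""
    n, c, h, w = x.shape
    idx = x.data.argmax(axis=1)  # (n,h,w)

    def bw_max(g):
        dx = np.zeros_like(x.data)
        ni, hi, wi = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
        np.add.at(dx, (ni, idx, hi, wi), g[:, 0])
        x._accum(dx)

    mx = Tensor._make(np.take_along_axis(x.data, idx[:, None], axis=1), (x,), bw_max)
    mean = x.mean(axis=1, keepdims=True)
    return ag.concat([mx, mean], axis=1)


@dataclass
class FDFFConfig:
    spectrum_mode: str = "real_only"
    pool_kernel: int = 3
    pool_stride: int = 1
    dsc_kernel: int = 3
    attn_kernel: int = 7
    hidden: int | None = None   # expansion width; default 2*C - 2 (calibrated)
    act: bool = True            # SiLU between fusion stages


class FDFF(nn.Module):
    """The full frequency-domain feature-fusion block (shape-preserving).

    Pipeline: DFT -> real part -> frequency max-pool -> multiply with the
    spatial input -> concat with the spatial input -> separable fusion conv
    (1x1 expand, depthwise, 1x1 project + BN) -> spatial attention gate.
    """

    def __init__(self, c1: int, c_out: int | None = None,
                 cfg: FDFFConfig | None = None, rng=None):
        cfg = cfg or FDFFConfig()
        if cfg.spectrum_mode not in SPECTRUM_MODES:
            raise ValueError(f"unknown spectrum mode {cfg.spectrum_mode!r}")
        if cfg.pool_stride != 1:
            raise ValueError("frequency max-pool must preserve extents "
                             "(stride 1) for multiplicative fusion")
        if cfg.pool_kernel % 2 != 1:
            raise ValueError("pooling kernel must be odd")
        c_out = c_out or c1
        self.c1, self.c_out, self.cfg = c1, c_out, cfg
        mult = 2 if cfg.spectrum_mode == "real_and_imag" else 1
        cin_f = c1 * (mult + 1)          # fused stack: [X_MS, X_S]
        h = cfg.hidden if cfg.hidden is not None else 2 * c1 - 2
        self.hidden = h
        self.expand = nn.Conv2d(cin_f, h, 1, bias=False, rng=rng)
        self.dw = nn.Conv2d(h, h, cfg.dsc_kernel, bias=False, depthwise=True, rng=rng)
        self.project = nn.Conv2d(h, c_out, 1, bias=True, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)
        self.attn = SpatialAttention(cfg.attn_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if cfg.spectrum_mode == "real_only":
            xf = ag.fft2_real(x)
        elif cfg.spectrum_mode == "imag_only":
            xf = ag.fft2_imag(x)
        else:
            xf = ag.concat([ag.fft2_real(x), ag.fft2_imag(x)], axis=1)
        xm = ag.maxpool2d(xf, cfg.pool_kernel, cfg.pool_stride, cfg.pool_kernel // 2)
        xs = x if cfg.spectrum_mode != "real_and_imag" else ag.concat([x, x], axis=1)
        xms = xm * xs
        z = ag.concat([xms, x], axis=1)
        z = self.expand(z)
        if cfg.act:
            z = z.silu()
        z = self.dw(z)
        if cfg.act:
            z = z.silu()
        z = self.bn(self.project(z))
        if cfg.act:
            z = z.silu()
        return z * self.attn(z)
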