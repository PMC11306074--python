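"""Neural-network modules on top of the autograd engine.

Contains the standard building blocks of the nano detector family:
``ConvBNSiLU`` ("CBS": bias-free conv + batch-norm + SiLU), ``Bottleneck``,
``C3`` and ``SPPF``, plus ``Linear``/``LayerNorm`` used by the transformer
blocks.

Parameter accounting follows the ecosystem convention of reporting deploy
counts: a CBS block counts its conv weights plus one bias per output channel
(the batch-norm affine/statistics fold into the convolution at inference
time), while custom modules (layer-norms, stand-alone batch-norms) count
as-is. ``Module.deploy_params()`` implements this rule; raw trainable counts
are available via ``Module.raw_params()``.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def autopad(k: int, p: int | None = None) -> int:
    return k // 2 if p is None else p


class Module:
    training: bool = True

    # -- traversal ------------------------------------------------------------
    def children(self):
        for k, v in vars(self).items():
            if isinstance(v, Module):
                yield k, v
            elif isinstance(v, (list, tuple)):
                for i, x in enumerate(v):
                    if isinstance(x, Module):
                        yield f"{k}.{i}", x

    def named_parameters(self, prefix: str = ""):
        for k, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield (f"{prefix}{k}", v)
        for name, child in self.children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for k, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield (f"{prefix}{k}", v)
        for name, child in self.children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def train(self, flag: bool = True):
        self.training = flag
        for _, c in self.children():
            c.train(flag)
        return self

    def all_modules(self):
        yield self
        for _, c in self.children():
            yield from c.all_modules()

    def eval(self):
        return self.train(False)

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self) -> dict:
        d = {k: p.data for k, p in self.named_parameters()}
        d.update({f"buf::{k}": v for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        for k, p in self.named_parameters():
            p.data = np.asarray(d[k], dtype=np.float32)
        for k, v in self.named_buffers():
            v[...] = d[f"buf::{k}"]

    # -- parameter accounting ---------------------------------------------------
    def raw_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def deploy_params(self) -> int:
        """BN-folded parameter count (see module docstring)."""
        own = sum(p.data.size for k, p in vars(self).items()
                  if isinstance(p, Tensor) and p.requires_grad)
        return int(own + sum(c.deploy_params() for _, c in self.children()))

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


def kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(3.0) * math.sqrt(2.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Plain convolution (optionally depthwise via groups=channels)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, bias: bool = True, depthwise: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.p = autopad(k, p)
        self.depthwise = depthwise
        if depthwise:
            assert c1 == c2, "depthwise conv preserves channel count"
            fan = k * k
            self.w = Tensor(kaiming(rng, (c1, k, k), fan), requires_grad=True)
        else:
            fan = c1 * k * k
            self.w = Tensor(kaiming(rng, (c2, c1, k, k), fan), requires_grad=True)
        self.b = Tensor(np.zeros(c2, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.depthwise:
            return ag.depthwise_conv2d(x, self.w, self.b, self.s, self.p)
        return ag.conv2d(x, self.w, self.b, self.s, self.p)


class BatchNorm2d(Module):
    """Batch normalisation with optional exact-statistics recalibration.

    ``begin_recalibration``/``end_recalibration`` switch the running
    statistics to a cumulative average over subsequent training-mode
    forwards ("precise BN"), which removes the running-average lag that
    short training runs leave behind.
    """

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float64)
        self.running_var = np.ones(c, np.float64)
        self.eps, self.momentum = eps, momentum
        self._recal_n = -1  # -1: normal EMA; >=0: cumulative average counter

    def begin_recalibration(self):
        self.running_mean[...] = 0.0
        self.running_var[...] = 0.0
        self._recal_n = 0

    def end_recalibration(self):
        if self._recal_n == 0:  # nothing accumulated; keep safe defaults
            self.running_var[...] = 1.0
        self._recal_n = -1

    def forward(self, x: Tensor) -> Tensor:
        if self.training and self._recal_n >= 0:
            momentum = 1.0 / (self._recal_n + 1)
            self._recal_n += 1
        else:
            momentum = self.momentum
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              momentum, self.eps)


class ConvBNSiLU(Module):
    """CBS unit: bias-free conv + batch-norm + SiLU (the detector's workhorse).

    Deploy count = conv weights + c2 (BN folds into a conv bias).
    """

    def __init__(self, c1, c2, k=1, s=1, p=None, act=True, rng=None):
        self.conv = Conv2d(c1, c2, k, s, p, bias=False, rng=rng)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y

    def deploy_params(self) -> int:
        return int(self.conv.w.data.size + self.conv.c2)


class Linear(Module):
    def __init__(self, ci: int, co: int, bias: bool = True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(kaiming(rng, (ci, co), ci), requires_grad=True)
        self.b = Tensor(np.zeros(co, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(d, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.layernorm(x, self.gamma, self.beta)


class Bottleneck(Module):
    """Residual 1x1 -> 3x3 pair used inside C3."""

    def __init__(self, c1, c2, shortcut=True, rng=None):
        self.cv1 = ConvBNSiLU(c1, c2, 1, rng=rng)
        self.cv2 = ConvBNSiLU(c2, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """CSP bottleneck container with three 1x1 convs."""

    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5, rng=None):
        ch = int(c2 * e)
        self.ch = ch
        self.cv1 = ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv2 = ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv3 = ConvBNSiLU(2 * ch, c2, 1, rng=rng)
        self.m = [Bottleneck(ch, ch, shortcut, rng=rng) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for blk in self.m:
            y = blk(y)
        return self.cv3(ag.concat([y, self.cv2(x)], axis=1))


class SPPF(Module):
    """Fast spatial pyramid pooling (three chained 5x5 max-pools)."""

    def __init__(self, c1, c2, k=5, rng=None):
        ch = c1 // 2
        self.cv1 = ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv2 = ConvBNSiLU(ch * 4, c2, 1, rng=rng)
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        x = self.cv1(x)
        p = self.k // 2
        y1 = ag.maxpool2d(x, self.k, 1, p)
        y2 = ag.maxpool2d(y1, self.k, 1, p)
        y3 = ag.maxpool2d(y2, self.k, 1, p)
        return self.cv2(ag.concat([x, y1, y2, y3], axis=1))
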