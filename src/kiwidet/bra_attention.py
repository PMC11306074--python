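"""Bi-level Routing Attention (BRA), the BiFormer block and C3BiF.

BRA makes self-attention sparse in two stages. The token map is first split
into an S x S grid of square regions; a region-level affinity matrix
A = Q_r K_r^T (region descriptors are mean-pooled queries/keys) is sparsified
by keeping, for every region, only its top-k most affine regions. Fine
token-to-token attention is then evaluated only against tokens gathered from
those routed regions, so the number of query-key pairs drops from tokens^2
to tokens * topk * tokens_per_region, with graceful degradation to full
global attention at topk = S^2.

The BiFormer block wraps BRA in the usual transformer skeleton:

    x = x + DWConv3x3(x)                 # convolutional position encoding
    x = x + BRA(LN(x))                   # with a 5x5 depthwise local-context
    x = x + MLP(LN(x))                   # enhancement added to V's output

and C3BiF plants one BiFormer block inside the C3 container (two parallel
1x1 reductions, concat, 1x1 expansion) in place of the bottleneck stack.

Trainable parameters of the block at token dim d are exactly 12 d^2 + 49 d
(qkv 3d^2+3d, output projection d^2+d, MLP ratio 4 8d^2+5d, two layer-norms
4d, positional depthwise 3x3 10d, local-context depthwise 5x5 26d) - the
budget implied by the published model totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from . import nn


# ---------------------------------------------------------------------------
# region partitioning
# ---------------------------------------------------------------------------

@dataclass
class RegionGrid:
    """S^2 non-overlapping square regions in row-major order; tokens within
    a region are row-major as well."""
    tokens: np.ndarray   # (N, S^2, T, d)
    side: int
    h: int
    w: int


@dataclass
class RoutingIndex:
    adjacency: np.ndarray  # (N, S^2, S^2) region affinity
    topk: int
    index: np.ndarray      # (N, S^2, topk) routed region ids


def _partition_t(x: Tensor, side: int) -> Tensor:
    """(N,C,H,W) -> (N, S^2, T, C) with autograd support."""
    n, c, h, w = x.shape
    for name, ext in (("height", h), ("width", w)):
        if ext % side != 0:
            raise ValueError(f"{name} {ext} is not divisible by region side {side}")
    hr, wr = h // side, w // side
    t = x.transpose(0, 2, 3, 1)                               # N,H,W,C
    t = t.reshape(n, side, hr, side, wr, c)
    t = t.transpose(0, 1, 3, 2, 4, 5)                          # N,S,S,hr,wr,C
    return t.reshape(n, side * side, hr * wr, c)


def _merge_t(tok: Tensor, side: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`_partition_t`."""
    n, r, t, c = tok.shape
    hr, wr = h // side, w // side
    y = tok.reshape(n, side, side, hr, wr, c)
    y = y.transpose(0, 1, 3, 2, 4, 5)
    y = y.reshape(n, h, w, c)
    return y.transpose(0, 3, 1, 2)


def partition_regions(x: np.ndarray, side: int) -> RegionGrid:
    """Split an (N,C,H,W) map into an S x S grid of token groups."""
    x = np.asarray(x, dtype=np.float32)
    tok = _partition_t(Tensor(x), side).data
    return RegionGrid(tokens=tok, side=side, h=x.shape[2], w=x.shape[3])


def merge_regions(grid: RegionGrid) -> np.ndarray:
    """Reassemble the (N,C,H,W) map from a region grid (exact inverse)."""
    return _merge_t(Tensor(grid.tokens), grid.side, grid.h, grid.w).data


def coarse_route(q_regions: np.ndarray, k_regions: np.ndarray, topk: int) -> RoutingIndex:
    """Region-level routing: descriptor affinity + row-wise top-k.

    Descriptors are the per-region token means of Q and K; ties in the
    affinity break toward the lower region id (deterministic).
    """
    qr = np.asarray(q_regions).mean(axis=2)    # (N,R,d)
    kr = np.asarray(k_regions).mean(axis=2)
    a = qr @ kr.swapaxes(-1, -2)               # (N,R,R)
    r = a.shape[-1]
    if not (1 <= topk <= r):
        raise ValueError(f"topk must be in [1, {r}], got {topk}")
    idx = _topk_lowid(a, topk)
    return RoutingIndex(adjacency=a, topk=topk, index=idx)


def _topk_lowid(a: np.ndarray, k: int) -> np.ndarray:
    """Row-wise top-k of the last axis; ties broken by lower index."""
    order = np.argsort(-a, axis=-1, kind="stable")
    return order[..., :k]


def attention_pair_count(h: int, w: int, side: int, topk: int) -> int:
    """Query-key pairs evaluated by BRA (== tokens^2 iff topk == side^2)."""
    tokens = h * w
    per_region = (h // side) * (w // side)
    return tokens * topk * per_region


# ---------------------------------------------------------------------------
# fine attention
# ---------------------------------------------------------------------------

def _fine_attention_t(q: Tensor, k: Tensor, v: Tensor, idx: np.ndarray,
                      heads: int) -> Tensor:
    """Routed multi-head attention on partitioned tokens.

    q,k,v: (N, R, T, d); idx: (N, R, topk). Returns (N, R, T, d).
    """
    n, r, t, d = q.shape
    if d % heads != 0:
        raise ValueError(f"token dim {d} not divisible by heads {heads}")
    dh = d // heads
    topk = idx.shape[-1]
    kg = ag.gather_regions(k, idx).reshape(n, r, topk * t, d)
    vg = ag.gather_regions(v, idx).reshape(n, r, topk * t, d)
    # split heads: (N,R,T,heads,dh) -> (N,R,heads,T,dh)
    qh = q.reshape(n, r, t, heads, dh).transpose(0, 1, 3, 2, 4)
    kh = kg.reshape(n, r, topk * t, heads, dh).transpose(0, 1, 3, 4, 2)
    vh = vg.reshape(n, r, topk * t, heads, dh).transpose(0, 1, 3, 2, 4)
    att = ag.softmax((qh @ kh) * (1.0 / np.sqrt(dh)), axis=-1)
    out = att @ vh                                            # N,R,heads,T,dh
    return out.transpose(0, 1, 3, 2, 4).reshape(n, r, t, d)


def fine_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                   route: RoutingIndex, heads: int) -> np.ndarray:
    """Numpy front-end of routed attention (q,k,v: (N,R,T,d) region tokens)."""
    out = _fine_attention_t(Tensor(np.asarray(q, np.float32)),
                            Tensor(np.asarray(k, np.float32)),
                            Tensor(np.asarray(v, np.float32)),
                            route.index, heads)
    return out.data


def default_side(h: int, w: int, max_side: int = 8, min_tokens: int = 4) -> int:
    """Largest region grid side <= max_side dividing both extents while
    keeping at least ``min_tokens`` tokens per region."""
    for s in range(max_side, 0, -1):
        if h % s == 0 and w % s == 0 and (h // s) * (w // s) >= min_tokens:
            return s
    return 1


def default_heads(d: int, max_heads: int = 8) -> int:
    for hds in range(max_heads, 0, -1):
        if d % hds == 0:
            return hds
    return 1


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

@dataclass
class BRAConfig:
    side: int | None = None    # region grid side S; None = adaptive (<= 8)
    topk: int = 4              # routed regions per query region
    heads: int | None = None   # None = largest divisor of d that is <= 8
    mlp_ratio: int = 4


class BiFormerBlock(nn.Module):
    """Transformer block with bi-level routing attention (shape-preserving)."""

    def __init__(self, d: int, cfg: BRAConfig | None = None, rng=None):
        cfg = cfg or BRAConfig()
        self.d = d
        self.cfg = cfg
        self.heads = cfg.heads or default_heads(d)
        if d % self.heads != 0:
            raise ValueError(f"dim {d} not divisible by heads {self.heads}")
        self.cpe = nn.Conv2d(d, d, 3, bias=True, depthwise=True, rng=rng)
        self.ln1 = nn.LayerNorm(d)
        self.qkv = nn.Linear(d, 3 * d, bias=True, rng=rng)
        self.proj = nn.Linear(d, d, bias=True, rng=rng)
        self.lce = nn.Conv2d(d, d, 5, bias=True, depthwise=True, rng=rng)
        self.ln2 = nn.LayerNorm(d)
        self.fc1 = nn.Linear(d, cfg.mlp_ratio * d, bias=True, rng=rng)
        self.fc2 = nn.Linear(cfg.mlp_ratio * d, d, bias=True, rng=rng)

    def _bra(self, x_tokens: Tensor, h: int, w: int, side: int) -> Tensor:
        n, hw, d = x_tokens.shape
        qkv = self.qkv(self.ln1(x_tokens))                    # (N,HW,3d)
        q = qkv[:, :, 0:d]
        k = qkv[:, :, d:2 * d]
        v = qkv[:, :, 2 * d:3 * d]
        # local context enhancement on V (depthwise 5x5 in map space)
        vmap = v.reshape(n, h, w, d).transpose(0, 3, 1, 2)
        lce = self.lce(vmap).transpose(0, 2, 3, 1).reshape(n, hw, d)
        to_map = lambda t: t.reshape(n, h, w, d).transpose(0, 3, 1, 2)
        qp = _partition_t(to_map(q), side)
        kp = _partition_t(to_map(k), side)
        vp = _partition_t(to_map(v), side)
        topk = min(self.cfg.topk, side * side)
        route = coarse_route(qp.data, kp.data, topk)          # indices: no grad
        o = _fine_attention_t(qp, kp, vp, route.index, self.heads)
        o = _merge_t(o, side, h, w).transpose(0, 2, 3, 1).reshape(n, hw, d)
        return self.proj(o + lce)

    def forward(self, x: Tensor) -> Tensor:
        n, d, h, w = x.shape
        side = self.cfg.side or default_side(h, w)
        x = x + self.cpe(x)
        t = x.transpose(0, 2, 3, 1).reshape(n, h * w, d)
        t = t + self._bra(t, h, w, side)
        t = t + self.fc2(self.fc1(self.ln2(t)).silu())
        return t.reshape(n, h, w, d).transpose(0, 3, 1, 2)


class C3BiF(nn.Module):
    """C3 container whose bottleneck stack is one BiFormer block.

    Drop-in replacement for a head C3: identical channel contract; the
    attention operates at the container's hidden width c2/2.
    """

    def __init__(self, c1: int, c2: int, cfg: BRAConfig | None = None, rng=None):
        ch = c2 // 2
        self.ch = ch
        self.cv1 = nn.ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv2 = nn.ConvBNSiLU(c1, ch, 1, rng=rng)
        self.cv3 = nn.ConvBNSiLU(2 * ch, c2, 1, rng=rng)
        self.m = BiFormerBlock(ch, cfg, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.cv3(ag.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


def biformer_param_count(d: int, mlp_ratio: int = 4) -> int:
    """Closed form for the block's trainable parameters: 12d^2 + 49d at
    mlp_ratio 4 (3d^2+3d qkv, d^2+d proj, 2*mlp*d^2+(mlp+1)d MLP, 4d norms,
    10d positional dwconv, 26d local-context dwconv)."""
    return (3 * d * d + 3 * d) + (d * d + d) + (2 * mlp_ratio * d * d + (mlp_ratio + 1) * d) \
        + 4 * d + 10 * d + 26 * d
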