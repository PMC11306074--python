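"""Model assembly and the parameter-audit harness.

Builds the nano-scale single-stage detector family: a CSP backbone
(CBS/C3 stacks over stages P1..P5 plus SPPF), an FPN+PAN neck and three
anchor-based heads at strides 8/16/32. Two architectural upgrades are
configurable:

* an FDFF block inserted after one of the backbone's stage convolutions
  ("the next layer of Pn"; default P3), and
* C3BiF substituted for a subset of the four head C3 containers
  (default the first three).

``audit_params`` produces the machine-checkable parameter table. Totals are
reported in the deploy convention (batch-norm folded into the preceding
convolution, the way model summaries are printed by the YOLO ecosystem's
validation tools); with four classes the baseline audits to exactly
1,764,577, the FDFF variant to 1,790,195 and the full model to 1,816,147.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .bra_attention import BRAConfig, C3BiF
from .fdff import FDFF, FDFFConfig

CLASS_NAMES = ("Female", "Bud", "Male", "Success")

# anchor priors in input pixels (strides 8/16/32)
ANCHORS = np.array(
    [[[10, 13], [16, 30], [33, 23]],
     [[30, 61], [62, 45], [59, 119]],
     [[116, 90], [156, 198], [373, 326]]], dtype=np.float32)
STRIDES = (8, 16, 32)

_FDFF_POSITIONS = ("none", "P1", "P2", "P3", "P4", "P5")


@dataclass
class ModelConfig:
    """Architecture recipe.

    ``fdff_position`` names the backbone stage conv after which the FDFF
    block is inserted; ``c3bif_positions`` lists the head C3 indices (1-4)
    replaced by C3BiF.
    """
    n_classes: int = 4
    width_multiple: float = 0.25
    depth_multiple: float = 0.33
    fdff_position: str = "none"
    c3bif_positions: tuple = ()
    input_size: int = 640
    class_names: tuple = CLASS_NAMES
    fdff: FDFFConfig = field(default_factory=FDFFConfig)
    bra: BRAConfig = field(default_factory=BRAConfig)

    def __post_init__(self):
        if not (0 < self.width_multiple <= 1) or not (0 < self.depth_multiple <= 1):
            raise ValueError("width/depth multiples must lie in (0, 1]")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.fdff_position not in _FDFF_POSITIONS:
            raise ValueError(f"fdff_position must be one of {_FDFF_POSITIONS}")
        self.c3bif_positions = tuple(sorted(set(self.c3bif_positions)))
        if any(p not in (1, 2, 3, 4) for p in self.c3bif_positions):
            raise ValueError("c3bif_positions must be a subset of {1,2,3,4}")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if isinstance(self.fdff, dict):
            self.fdff = FDFFConfig(**self.fdff)
        if isinstance(self.bra, dict):
            self.bra = BRAConfig(**self.bra)
        self.class_names = tuple(self.class_names)

    # -- yaml round trip ------------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        d = yaml.safe_load(text)
        return cls(**d)


PRESETS = {}


def _register_presets():
    PRESETS["yolov5n"] = ModelConfig()
    for p in ("P1", "P2", "P3", "P4", "P5"):
        PRESETS[f"yolov5n-fdff-{p.lower()}"] = ModelConfig(fdff_position=p)
    for subset in ((1,), (2,), (3,), (1, 2), (2, 3), (1, 3), (1, 2, 3)):
        PRESETS["c3bif-" + "".join(map(str, subset))] = ModelConfig(
            fdff_position="P3", c3bif_positions=subset)
    PRESETS["yolov5n-c3bif"] = ModelConfig(c3bif_positions=(1, 2, 3))
    PRESETS["kiwi"] = ModelConfig(fdff_position="P3", c3bif_positions=(1, 2, 3))


_register_presets()


def _make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(np.ceil(x / divisor) * divisor))


class Detect(nn.Module):
    """Anchor-based prediction heads: one 1x1 conv (with bias) per level,
    emitting 3*(n_classes+5) channels."""

    def __init__(self, n_classes: int, chs, rng=None):
        self.nc = n_classes
        self.no = n_classes + 5
        self.m = [nn.Conv2d(c, 3 * self.no, 1, bias=True, rng=rng) for c in chs]

    def forward(self, xs):
        return [conv(x) for conv, x in zip(self.m, xs)]


class KiwiModel(nn.Module):
    """The assembled detector: named layer graph with skip connections."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        gw = lambda c: _make_divisible(c * cfg.width_multiple)
        gd = lambda n: max(round(n * cfg.depth_multiple), 1)
        c64, c128, c256, c512, c1024 = (gw(c) for c in (64, 128, 256, 512, 1024))
        self.channels = dict(P1=c64, P2=c128, P3=c256, P4=c512, P5=c1024)

        seq: list[tuple[str, object, tuple]] = []  # (name, module/op, from_names)

        def add(name, module, frm=("prev",)):
            seq.append((name, module, frm))

        add("conv_p1", nn.ConvBNSiLU(3, c64, 6, 2, p=2, rng=rng))
        self._maybe_fdff(add, "P1", c64, rng)
        add("conv_p2", nn.ConvBNSiLU(c64, c128, 3, 2, rng=rng))
        self._maybe_fdff(add, "P2", c128, rng)
        add("c3_b2", nn.C3(c128, c128, gd(3), rng=rng))
        add("conv_p3", nn.ConvBNSiLU(c128, c256, 3, 2, rng=rng))
        self._maybe_fdff(add, "P3", c256, rng)
        add("c3_b4", nn.C3(c256, c256, gd(6), rng=rng))
        add("conv_p4", nn.ConvBNSiLU(c256, c512, 3, 2, rng=rng))
        self._maybe_fdff(add, "P4", c512, rng)
        add("c3_b6", nn.C3(c512, c512, gd(9), rng=rng))
        add("conv_p5", nn.ConvBNSiLU(c512, c1024, 3, 2, rng=rng))
        self._maybe_fdff(add, "P5", c1024, rng)
        add("c3_b8", nn.C3(c1024, c1024, gd(3), rng=rng))
        add("sppf", nn.SPPF(c1024, c1024, 5, rng=rng))

        def head_c3(pos, c1, c2):
            if pos in cfg.c3bif_positions:
                return C3BiF(c1, c2, cfg.bra, rng=rng)
            return nn.C3(c1, c2, gd(3), shortcut=False, rng=rng)

        add("neck_conv1", nn.ConvBNSiLU(c1024, c512, 1, 1, rng=rng))
        add("up1", "upsample")
        add("cat1", "concat", ("prev", "c3_b6"))
        add("head_c3_1", head_c3(1, c1024, c512))
        add("neck_conv2", nn.ConvBNSiLU(c512, c256, 1, 1, rng=rng))
        add("up2", "upsample")
        add("cat2", "concat", ("prev", "c3_b4"))
        add("head_c3_2", head_c3(2, c512, c256))      # -> P3 out (stride 8)
        add("down1", nn.ConvBNSiLU(c256, c256, 3, 2, rng=rng))
        add("cat3", "concat", ("prev", "neck_conv2"))
        add("head_c3_3", head_c3(3, c512, c512))      # -> P4 out (stride 16)
        add("down2", nn.ConvBNSiLU(c512, c512, 3, 2, rng=rng))
        add("cat4", "concat", ("prev", "neck_conv1"))
        add("head_c3_4", head_c3(4, c1024, c1024))    # -> P5 out (stride 32)

        self.seq = seq
        self.layers = [m for _, m, _ in seq if isinstance(m, nn.Module)]
        self.detect = Detect(cfg.n_classes, (c256, c512, c1024), rng=rng)
        self.out_names = ("head_c3_2", "head_c3_3", "head_c3_4")

    def _maybe_fdff(self, add, stage: str, c: int, rng):
        if self.cfg.fdff_position == stage:
            add(f"fdff_{stage.lower()}", FDFF(c, c, self.cfg.fdff, rng=rng))

    # -- forward ---------------------------------------------------------------
    def forward(self, x: Tensor, capture: dict | None = None):
        """Run the graph; returns the three raw head maps (strides 8/16/32).

        ``capture`` (optional dict) receives named intermediate activations,
        used by Grad-CAM.
        """
        acts: dict[str, Tensor] = {}
        prev = x
        for name, module, frm in self.seq:
            if module == "upsample":
                prev = ag.upsample2x(prev)
            elif module == "concat":
                srcs = [prev if f == "prev" else acts[f] for f in frm]
                prev = ag.concat(srcs, axis=1)
            else:
                prev = module(prev)
            acts[name] = prev
            if capture is not None:
                capture[name] = prev
        outs = self.detect([acts[n] for n in self.out_names])
        if capture is not None:
            for n, o in zip(("out_p3", "out_p4", "out_p5"), outs):
                capture[n] = o
        return outs

    def layer_names(self):
        return [name for name, _, _ in self.seq] + ["detect"]


def build_model(cfg: ModelConfig, seed: int = 0) -> KiwiModel:
    """Construct (and randomly initialise) a detector from a config."""
    return KiwiModel(cfg, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# parameter audit
# ---------------------------------------------------------------------------

@dataclass
class ParamAudit:
    per_layer: list          # [(layer name, deploy count)]
    total: int               # deploy (BN-folded) total - the published convention
    raw_total: int           # raw trainable count (BN affine included)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("layer,parameters\n")
        for name, n in self.per_layer:
            buf.write(f"{name},{n}\n")
        buf.write(f"TOTAL,{self.total}\n")
        return buf.getvalue()


def audit_params(model: KiwiModel) -> ParamAudit:
    """Exact per-layer and total parameter counts (shape-only, seed-free)."""
    per = []
    for name, module, _ in model.seq:
        if isinstance(module, nn.Module):
            per.append((name, module.deploy_params()))
    per.append(("detect", model.detect.deploy_params()))
    total = int(sum(n for _, n in per))
    raw = int(sum(m.raw_params() for m in model.layers) + model.detect.raw_params())
    return ParamAudit(per_layer=per, total=total, raw_total=raw)


def ablation_table(cfgs, names=None, metrics=None) -> list[dict]:
    """Audit a sweep of configs; optional per-config metric dicts fill the
    metric columns (left blank when no dataset was evaluated)."""
    if not cfgs:
        raise ValueError("need at least one config")
    rows = []
    for i, cfg in enumerate(cfgs):
        audit = audit_params(build_model(cfg))
        row = {
            "name": names[i] if names else f"cfg{i}",
            "fdff": cfg.fdff_position,
            "c3bif": ",".join(map(str, cfg.c3bif_positions)) or "-",
            "parameters": audit.total,
        }
        row.update(metrics[i] if metrics and metrics[i] else
                   {"mAP50": "", "recall": ""})
        rows.append(row)
    return rows


def format_table(rows: list[dict]) -> str:
    cols = list(rows[0].keys())
    widths = {c: max(len(str(c)), *(len(str(r[c])) for r in rows)) for c in cols}
    lines = ["  ".join(str(c).ljust(widths[c]) for c in cols)]
    for r in rows:
        lines.append("  ".join(str(r[c]).ljust(widths[c]) for c in cols))
    return "\n".join(lines)
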