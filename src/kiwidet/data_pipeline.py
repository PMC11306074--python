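"""Dataset I/O, letterboxing, online augmentation and the synthetic
orchard-scene generator.

Labels use the plain-text YOLO format: one ``class cx cy w h`` row per
object with center-format box coordinates normalised to [0, 1]. The four
pollination-stage classes are Female=0, Bud=1, Male=2, Success=3.

The generator emulates bottom-up orchard photographs: a leafy green textured
background over which flower renderings are scattered (dense, partially
overlapping, small relative to the canvas) under low/normal/high
illumination. Class identity is carried by contour cues, mirroring how the
stages are told apart in the field: buds are near-circular discs, female
flowers are petal rosettes with a central stigma (radial spokes), male
flowers are rosettes with scattered stamen dots but no stigma, and the
pollinated state shows shed petals around a central young fruit. It is a
synthetic stand-in: no camera noise, bokeh or true lighting model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

CLASS_NAMES = ("Female", "Bud", "Male", "Success")
FEMALE, BUD, MALE, SUCCESS = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self, n_classes: int = 4) -> "Annotation":
        if not (0 <= self.class_id < n_classes):
            raise ValueError(f"class id {self.class_id} outside [0, {n_classes})")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width/height must be positive")
        for v in (self.cx, self.cy, self.w, self.h):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"coordinate {v} outside [0, 1]")
        return self

    def corners(self):
        """(x1, y1, x2, y2), normalised."""
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @staticmethod
    def from_corners(class_id, x1, y1, x2, y2, clip: bool = True):
        if clip:
            x1, y1 = max(x1, 0.0), max(y1, 0.0)
            x2, y2 = min(x2, 1.0), min(y2, 1.0)
        return Annotation(class_id, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


class LabelParseError(ValueError):
    pass


def read_labels(path, n_classes: int = 4) -> list[Annotation]:
    """Parse a YOLO label file; blank lines are ignored."""
    anns = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cid = int(parts[0])
            vals = [float(p) for p in parts[1:]]
        except ValueError as e:
            raise LabelParseError(f"{path}:{ln}: {e}") from e
        try:
            anns.append(Annotation(cid, *vals).validate(n_classes))
        except ValueError as e:
            raise LabelParseError(f"{path}:{ln}: {e}") from e
    return anns


def write_labels(path, annotations) -> None:
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}"
             for a in annotations]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# letterbox
# ---------------------------------------------------------------------------

@dataclass
class LetterboxTransform:
    scale: float
    pad_x: float
    pad_y: float
    src_w: int
    src_h: int
    target: int

    def box_to_target(self, ann: Annotation) -> Annotation:
        """Map a source-normalised annotation into the letterboxed frame."""
        cx = (ann.cx * self.src_w * self.scale + self.pad_x) / self.target
        cy = (ann.cy * self.src_h * self.scale + self.pad_y) / self.target
        w = ann.w * self.src_w * self.scale / self.target
        h = ann.h * self.src_h * self.scale / self.target
        return Annotation(ann.class_id, cx, cy, w, h)

    def box_to_source(self, ann: Annotation) -> Annotation:
        cx = (ann.cx * self.target - self.pad_x) / (self.src_w * self.scale)
        cy = (ann.cy * self.target - self.pad_y) / (self.src_h * self.scale)
        w = ann.w * self.target / (self.src_w * self.scale)
        h = ann.h * self.target / (self.src_h * self.scale)
        return Annotation(ann.class_id, cx, cy, w, h)


def letterbox(image: np.ndarray, target: int, pad_value: int = 114):
    """Aspect-preserving resize + symmetric grey padding to target x target.

    Returns the padded image and the affine transform for mapping boxes in
    both directions.
    """
    if target % 32 != 0:
        raise ValueError("target size must be divisible by 32")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    h, w = img.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("zero-sized image")
    scale = target / max(h, w)
    nw, nh = round(w * scale), round(h * scale)
    if (nw, nh) != (w, h):
        pil = Image.fromarray(img.astype(np.uint8))
        img = np.asarray(pil.resize((nw, nh), Image.BILINEAR))
    pad_x, pad_y = (target - nw) / 2, (target - nh) / 2
    out = np.full((target, target, 3), pad_value, dtype=np.uint8)
    x0, y0 = int(pad_x), int(pad_y)
    out[y0:y0 + nh, x0:x0 + nw] = img
    return out, LetterboxTransform(scale, x0, y0, w, h, target)


# ---------------------------------------------------------------------------
# online augmentation
# ---------------------------------------------------------------------------

MIN_BOX_PX = 2.0  # boxes degenerating below this side length are dropped


def mosaic(samples, seed=None, center=None, scale_range=(1.2, 2.0)):
    """Four-image mosaic: random per-image scaling, stitching around a random
    centre in the central half of a double-size canvas, then 2x reduction.

    ``samples``: four (image HxWx3 uint8, [Annotation]) pairs of equal size.
    Fixing ``center`` to the exact canvas centre with ``scale_range=(1, 1)``
    conserves every annotation (nothing is cropped). The default scale range
    is chosen > 1 so that the final 2x reduction leaves object scale close
    to the source scale on average.
    """
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly 4 samples")
    rng = np.random.default_rng(seed)
    s = samples[0][0].shape[0]
    canvas = np.full((2 * s, 2 * s, 3), 114, dtype=np.uint8)
    if center is None:
        cx = int(rng.uniform(0.5 * s, 1.5 * s))
        cy = int(rng.uniform(0.5 * s, 1.5 * s))
    else:
        cx, cy = center
    out_anns: list[Annotation] = []
    for i, (img, anns) in enumerate(samples):
        k = float(rng.uniform(*scale_range))
        ih, iw = img.shape[:2]
        nw, nh = max(round(iw * k), 1), max(round(ih * k), 1)
        if (nw, nh) != (iw, ih):
            img = np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
        # anchor each image to the stitch centre (TL, TR, BL, BR)
        if i == 0:
            x1, y1 = cx - nw, cy - nh
        elif i == 1:
            x1, y1 = cx, cy - nh
        elif i == 2:
            x1, y1 = cx - nw, cy
        else:
            x1, y1 = cx, cy
        # visible region on canvas
        vx1, vy1 = max(x1, 0), max(y1, 0)
        vx2, vy2 = min(x1 + nw, 2 * s), min(y1 + nh, 2 * s)
        if vx2 <= vx1 or vy2 <= vy1:
            continue
        canvas[vy1:vy2, vx1:vx2] = img[vy1 - y1:vy2 - y1, vx1 - x1:vx2 - x1]
        for a in anns:
            bx1, by1, bx2, by2 = a.corners()
            px1, py1 = bx1 * nw + x1, by1 * nh + y1
            px2, py2 = bx2 * nw + x1, by2 * nh + y1
            px1, py1 = max(px1, vx1), max(py1, vy1)
            px2, py2 = min(px2, vx2), min(py2, vy2)
            if px2 - px1 < MIN_BOX_PX or py2 - py1 < MIN_BOX_PX:
                continue
            out_anns.append(Annotation.from_corners(
                a.class_id, px1 / (2 * s), py1 / (2 * s), px2 / (2 * s), py2 / (2 * s)))
    out = np.asarray(Image.fromarray(canvas).resize((s, s), Image.BILINEAR))
    return out, out_anns


def mixup(sample_a, sample_b, w: float):
    """Weighted pixelwise blend w*a + (1-w)*b; annotation lists concatenate."""
    (ia, aa), (ib, ab) = sample_a, sample_b
    if ia.shape != ib.shape:
        raise ValueError(f"mixup shape mismatch: {ia.shape} vs {ib.shape}")
    img = (w * ia.astype(np.float32) + (1.0 - w) * ib.astype(np.float32))
    return np.clip(img, 0, 255).astype(np.uint8), list(aa) + list(ab)


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Conditions of one synthetic orchard scene."""
    n_objects: int = 10
    class_ratio: tuple = (3, 3, 2, 2)          # Female : Bud : Male : Success
    illumination: str = "normal"               # low / normal / high
    size_range: tuple = (0.09, 0.20)           # object diameter as canvas fraction
    occlusion_rate: float = 0.15               # chance a crowded placement is kept
    canvas: int = 640
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.class_ratio):
            raise ValueError("class ratio entries must be positive")
        if not (0.0 <= self.occlusion_rate < 1.0):
            raise ValueError("occlusion_rate must lie in [0, 1)")
        if self.illumination not in ("low", "normal", "high"):
            raise ValueError("illumination must be low/normal/high")


_GAIN = {"low": 0.55, "normal": 1.0, "high": 1.45}


class SceneGenerationError(RuntimeError):
    pass


def _background(rng: np.random.Generator, s: int) -> np.ndarray:
    """Leafy green texture: smooth low-frequency mottling + leaf ellipses."""
    small = rng.uniform(0.0, 1.0, size=(s // 16, s // 16))
    coarse = np.asarray(Image.fromarray((small * 255).astype(np.uint8))
                        .resize((s, s), Image.BILINEAR), dtype=np.float32) / 255.0
    img = np.empty((s, s, 3), np.float32)
    img[..., 0] = 40 + 45 * coarse
    img[..., 1] = 85 + 70 * coarse
    img[..., 2] = 35 + 40 * coarse
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    for _ in range(max(6, s // 80)):
        ex, ey = rng.uniform(0, s, 2)
        ea, eb = rng.uniform(0.04 * s, 0.12 * s, 2)
        th = rng.uniform(0, math.pi)
        dx, dy = xx - ex, yy - ey
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        mask = (u / ea) ** 2 + (v / eb) ** 2 < 1.0
        shade = rng.uniform(0.75, 0.95)
        img[mask] *= shade
    return img


def _render_flower(img: np.ndarray, cid: int, cx: float, cy: float, radius: float,
                   rng: np.random.Generator) -> tuple:
    """Draw one flower; returns its tight pixel bounding box (x1,y1,x2,y2)."""
    s = img.shape[0]
    r = radius
    x0, x1 = int(max(cx - 1.3 * r, 0)), int(min(cx + 1.3 * r, s))
    y0, y1 = int(max(cy - 1.3 * r, 0)), int(min(cy + 1.3 * r, s))
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
    dx, dy = xx - cx, yy - cy
    rho = np.sqrt(dx * dx + dy * dy)
    theta = np.arctan2(dy, dx)
    patch = img[y0:y1, x0:x1]
    drawn = np.zeros(rho.shape, bool)

    def paint(mask, color, alpha=1.0):
        for c in range(3):
            patch[..., c][mask] = (1 - alpha) * patch[..., c][mask] + alpha * color[c]
        drawn[mask] = True

    if cid == BUD:
        # near-circular filled disc, pale yellow-green
        ecc = rng.uniform(0.85, 1.0)
        mask = (dx / r) ** 2 + (dy / (r * ecc)) ** 2 < 1.0
        paint(mask, (205, 215, 150))
        paint((dx / r) ** 2 + (dy / (r * ecc)) ** 2 < 0.35, (225, 230, 170))
    elif cid in (FEMALE, MALE):
        # petal rosette: k-lobed polar rose
        k = int(rng.integers(6, 9))
        phase = rng.uniform(0, 2 * math.pi)
        lobe = 0.55 + 0.45 * np.abs(np.cos(k * (theta + phase) / 2.0))
        paint(rho < r * lobe, (240, 238, 225))
        if cid == FEMALE:
            # central stigma: thin radial spokes + bright centre
            spokes = (np.abs(np.sin((theta + phase) * k)) < 0.22) & (rho < 0.55 * r)
            paint(spokes, (250, 245, 160))
            paint(rho < 0.18 * r, (250, 250, 190))
        else:
            # dense dark anther ring instead of a stigma (the cue must stay
            # legible after downsampling, so it is an area not a dot pattern)
            paint(rho < 0.45 * r, (150, 120, 45))
            for _ in range(10):
                ang, rr = rng.uniform(0, 2 * math.pi), rng.uniform(0.1, 0.4) * r
                px, py = cx + rr * math.cos(ang), cy + rr * math.sin(ang)
                dot = (xx - px) ** 2 + (yy - py) ** 2 < (0.12 * r) ** 2
                paint(dot, (110, 80, 30))
    else:  # SUCCESS: shed petals + central young fruit
        k = int(rng.integers(2, 4))
        phase = rng.uniform(0, 2 * math.pi)
        for i in range(k):
            ang = phase + i * 2 * math.pi / k + rng.uniform(-0.4, 0.4)
            px, py = cx + 0.75 * r * math.cos(ang), cy + 0.75 * r * math.sin(ang)
            petal = ((xx - px) / (0.35 * r)) ** 2 + ((yy - py) / (0.2 * r)) ** 2 < 1.0
            paint(petal, (225, 215, 190), alpha=0.9)
        fruit = (dx / (0.5 * r)) ** 2 + (dy / (0.62 * r)) ** 2 < 1.0
        paint(fruit, (140, 150, 70))
        paint((dx / (0.2 * r)) ** 2 + (dy / (0.3 * r)) ** 2 < 1.0, (160, 170, 85))

    ys, xs = np.nonzero(drawn)
    if len(xs) == 0:
        return None
    return (x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1, y0 + ys.max() + 1)


def _iou_xyxy(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def synthesize_scene(spec: SceneSpec):
    """Render one scene; deterministic in ``spec`` (including its seed).

    Returns (image uint8 HxWx3, [Annotation]).
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.canvas
    img = _background(rng, s)
    ratio = np.asarray(spec.class_ratio, np.float64)
    probs = ratio / ratio.sum()
    anns: list[Annotation] = []
    placed: list[tuple] = []
    for _ in range(spec.n_objects):
        cid = int(rng.choice(4, p=probs))
        ok = False
        for _try in range(120):
            frac = rng.uniform(*spec.size_range)
            r = frac * s / 2
            cx = rng.uniform(r, s - r)
            cy = rng.uniform(r, s - r)
            cand = (cx - r, cy - r, cx + r, cy + r)
            worst = max((_iou_xyxy(cand, p) for p in placed), default=0.0)
            if worst < 0.05 or (worst <= 0.4 and rng.uniform() < spec.occlusion_rate):
                ok = True
                break
        if not ok:
            raise SceneGenerationError(
                f"could not place object {len(anns)} within the occlusion budget")
        bbox = _render_flower(img, cid, cx, cy, r, rng)
        if bbox is None:
            continue
        placed.append(bbox)
        x1, y1, x2, y2 = bbox
        anns.append(Annotation.from_corners(cid, x1 / s, y1 / s, x2 / s, y2 / s)
                    .validate())
    gain = _GAIN[spec.illumination]
    img = np.clip(img * gain, 0, 255).astype(np.uint8)
    return img, anns


def synthesize_dataset(n_scenes: int, seed: int, **spec_kw):
    """n scenes with per-scene derived seeds; illumination cycles
    low/normal/high to mirror the three capture conditions."""
    illum = ("low", "normal", "high")
    out = []
    for i in range(n_scenes):
        spec = SceneSpec(seed=(seed * 100003 + i) % (2 ** 31 - 1),
                         illumination=illum[i % 3], **spec_kw)
        out.append(synthesize_scene(spec))
    return out


# ---------------------------------------------------------------------------
# dataset on disk + split
# ---------------------------------------------------------------------------

def save_dataset(out_dir, scenes, manifest_extra: dict | None = None) -> None:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    for i, (img, anns) in enumerate(scenes):
        stem = f"scene_{i:05d}"
        Image.fromarray(img).save(out / "images" / f"{stem}.png")
        write_labels(out / "labels" / f"{stem}.txt", anns)
    manifest = {"images": "images", "labels": "labels",
                "names": list(CLASS_NAMES), "n": len(scenes)}
    manifest.update(manifest_extra or {})
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def load_dataset(root):
    root = Path(root)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    scenes = []
    for img_path in sorted((root / manifest["images"]).glob("*.png")):
        lab = root / manifest["labels"] / (img_path.stem + ".txt")
        img = np.asarray(Image.open(img_path).convert("RGB"))
        scenes.append((img, read_labels(lab) if lab.exists() else []))
    return scenes


def split_dataset(items, train_fraction: float, seed: int):
    """Disjoint, exhaustive, seed-deterministic train/test split.

    n_train = floor(n * train_fraction); the remainder is the test side
    (1594 items at 0.9 -> 1434 / 160).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(items) < 2:
        raise ValueError("need at least 2 items to split")
    idx = np.random.default_rng(seed).permutation(len(items))
    n_train = int(math.floor(len(items) * train_fraction))
    train = [items[i] for i in idx[:n_train]]
    test = [items[i] for i in idx[n_train:]]
    return train, test
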