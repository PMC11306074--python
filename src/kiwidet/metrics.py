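"""Detection evaluation: IoU, greedy matching, precision/recall/F1, AP, mAP.

Conventions: matches count at IoU >= 0.5 unless stated otherwise; matching
is greedy in descending confidence with a one-to-one constraint per class;
AP integrates the monotone (cumulative-max) precision envelope over all
operating points of the confidence sweep (continuous AP, not the 11-point
approximation); mAP is the unweighted mean of the per-class APs over classes
that have ground truth. mAP@0.5:0.95 averages mAP over IoU thresholds
0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class Detection:
    class_id: int
    box: tuple          # (x1, y1, x2, y2), normalised corners
    confidence: float

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"box must be well-ordered, got {self.box}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


def iou(a, b) -> float:
    """Intersection-over-union of two (x1,y1,x2,y2) boxes; 0 for disjoint or
    degenerate boxes (degeneracy is logged)."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    if area_a == 0.0 or area_b == 0.0:
        log.warning("degenerate (zero-area) box in IoU: %s vs %s", a, b)
        return 0.0
    ix = min(ax2, bx2) - max(ax1, bx1)
    iy = min(ay2, by2) - max(ay1, by1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (area_a + area_b - inter)


def _truth_box(t) -> tuple:
    """Accept Annotation-like (center format) or plain corner tuples."""
    if hasattr(t, "corners"):
        return t.corners()
    return tuple(t)


def _truth_class(t) -> int:
    return t.class_id if hasattr(t, "class_id") else int(t[4])


@dataclass
class MatchResult:
    tp: dict = field(default_factory=dict)   # per class
    fp: dict = field(default_factory=dict)
    fn: dict = field(default_factory=dict)
    matches: list = field(default_factory=list)  # (det index, truth index, IoU)

    def totals(self):
        return (sum(self.tp.values()), sum(self.fp.values()), sum(self.fn.values()))


def match_detections(dets, truths, iou_thresh: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching per class at the given IoU threshold.

    Detections are processed in descending confidence; each matches the
    highest-IoU not-yet-matched truth of its class with IoU >= threshold.
    Unmatched detections are FP, unmatched truths FN.
    """
    res = MatchResult()
    classes = {d.class_id for d in dets} | {_truth_class(t) for t in truths}
    for c in sorted(classes):
        res.tp[c] = res.fp[c] = 0
        res.fn[c] = 0
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    used = [False] * len(truths)
    for di in order:
        d = dets[di]
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if used[j] or _truth_class(t) != d.class_id:
                continue
            v = iou(d.box, _truth_box(t))
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thresh:
            used[best_j] = True
            res.tp[d.class_id] += 1
            res.matches.append((di, best_j, best_iou))
        else:
            res.fp[d.class_id] += 1
    for j, t in enumerate(truths):
        if not used[j]:
            res.fn[_truth_class(t)] += 1
    return res


def precision_recall_f1(m: MatchResult):
    """Aggregate P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R) as fractions
    (multiply by 100 for the percentage convention). 0/0 is defined as 0."""
    tp, fp, fn = m.totals()
    if min(tp, fp, fn) < 0:
        raise ValueError("negative counts")
    p = _safe_div(tp, tp + fp, "precision")
    r = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * p * r, p + r, "F1")
    return p, r, f1


def _safe_div(num, den, what: str) -> float:
    if den == 0:
        log.warning("0/0 in %s defined as 0", what)
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# AP / mAP over a dataset
# ---------------------------------------------------------------------------

def _score_detections(dets_by_image, truths_by_image, class_id: int,
                      iou_thresh: float):
    """Pooled (confidence, is-TP) pairs and ground-truth count for a class."""
    scores, n_gt = [], 0
    for dets, truths in zip(dets_by_image, truths_by_image):
        gts = [t for t in truths if _truth_class(t) == class_id]
        n_gt += len(gts)
        cdets = sorted((d for d in dets if d.class_id == class_id),
                       key=lambda d: -d.confidence)
        used = [False] * len(gts)
        for d in cdets:
            best_iou, best_j = 0.0, -1
            for j, t in enumerate(gts):
                if used[j]:
                    continue
                v = iou(d.box, _truth_box(t))
                if v > best_iou:
                    best_iou, best_j = v, j
            if best_j >= 0 and best_iou >= iou_thresh:
                used[best_j] = True
                scores.append((d.confidence, 1))
            else:
                scores.append((d.confidence, 0))
    return scores, n_gt


def average_precision(dets_by_image, truths_by_image, class_id: int,
                      iou_thresh: float = 0.5):
    """Continuous AP = area under the monotone precision envelope of the
    confidence sweep. Returns None when the class has no ground truth."""
    scores, n_gt = _score_detections(dets_by_image, truths_by_image,
                                     class_id, iou_thresh)
    if n_gt == 0:
        return None
    if not scores:
        return 0.0
    scores.sort(key=lambda s: -s[0])
    tps = np.array([s[1] for s in scores], dtype=np.float64)
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1.0 - tps)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone envelope, then rectangle sum over recall increments
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r, ap = 0.0, 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_average_precision(dets_by_image, truths_by_image, n_classes: int,
                           iou_thresh: float = 0.5):
    """Unweighted mean of per-class APs over classes with ground truth."""
    aps = {}
    for c in range(n_classes):
        ap = average_precision(dets_by_image, truths_by_image, c, iou_thresh)
        if ap is not None:
            aps[c] = ap
    if not aps:
        raise ValueError("no class has ground truth; mAP undefined")
    return float(np.mean(list(aps.values()))), aps


def map_50_95(dets_by_image, truths_by_image, n_classes: int):
    """mean over IoU thresholds 0.5:0.05:0.95 of mAP."""
    vals = []
    for t in np.arange(0.5, 0.96, 0.05):
        m, _ = mean_average_precision(dets_by_image, truths_by_image,
                                      n_classes, float(round(t, 2)))
        vals.append(m)
    return float(np.mean(vals))


def max_f1_operating_point(dets_by_image, truths_by_image, n_classes: int,
                           iou_thresh: float = 0.5):
    """Sweep the confidence threshold; return (P, R, F1, conf) at max F1.

    The printed recall/F1 of detector reports correspond to one operating
    point on the PR curve; this picks the F1-optimal one and labels it.
    """
    confs = sorted({d.confidence for dets in dets_by_image for d in dets},
                   reverse=True)
    best = (0.0, 0.0, 0.0, 1.0)
    for thr in confs:
        m_tp = m_fp = m_fn = 0
        for dets, truths in zip(dets_by_image, truths_by_image):
            kept = [d for d in dets if d.confidence >= thr]
            m = match_detections(kept, truths, iou_thresh)
            tp, fp, fn = m.totals()
            m_tp, m_fp, m_fn = m_tp + tp, m_fp + fp, m_fn + fn
        p = _safe_div(m_tp, m_tp + m_fp, "precision")
        r = _safe_div(m_tp, m_tp + m_fn, "recall")
        f1 = _safe_div(2 * p * r, p + r, "F1")
        if f1 > best[2]:
            best = (p, r, f1, thr)
    return best


def evaluation_report(dets_by_image, truths_by_image, n_classes: int = 4,
                      class_names=None) -> dict:
    """Full evaluation: per-class AP, mAP@0.5, mAP@0.5:0.95 and the max-F1
    operating point, as a JSON-serialisable dict."""
    m50, aps = mean_average_precision(dets_by_image, truths_by_image, n_classes)
    p, r, f1, conf = max_f1_operating_point(dets_by_image, truths_by_image, n_classes)
    names = class_names or [str(c) for c in range(n_classes)]
    return {
        "mAP50": m50,
        "mAP50_95": map_50_95(dets_by_image, truths_by_image, n_classes),
        "per_class_AP50": {names[c]: ap for c, ap in aps.items()},
        "precision": p, "recall": r, "f1": f1,
        "operating_point": "max-F1 confidence sweep",
        "confidence_at_max_f1": conf,
    }
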