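"""COCO-style detection metrics: AP50, recall and the F1 measure.

Matching is the COCO greedy rule: detections are processed in descending
score order and each claims the unmatched ground-truth box of highest
overlap, provided IoU >= threshold; everything else is a false positive.
AP50 pools detections over all images, sweeps the score-ordered list into
a precision-recall curve and averages interpolated precision at the 101
evenly spaced recall points of the COCO protocol.

The headline tables this package mirrors report F1 as the harmonic mean
of the AP50 percentage (precision surrogate) and the recall percentage,
rounded half-up to one decimal; :func:`f1` implements exactly that
arithmetic, and a score-thresholded precision/recall report is available
through :func:`match_detections` for the conventional reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "MatchResult",
    "iou",
    "match_detections",
    "average_precision_50",
    "recall",
    "f1",
    "load_coco_ground_truth",
    "load_coco_detections",
]


def _box(b) -> np.ndarray:
    """Normalise a box-like (x_min, y_min, x_max, y_max) to an array."""
    if hasattr(b, "box"):
        b = b.box
    arr = np.asarray(b, dtype=np.float64)
    if arr.shape == (5,):  # trailing score on a detection tuple
        arr = arr[:4]
    if arr.shape != (4,):
        raise ValueError(f"expected a 4-vector box, got shape {arr.shape}")
    return arr


def _score(d) -> float:
    if hasattr(d, "score"):
        return float(d.score)
    return float(d[4])


def iou(a, b) -> float:
    """Intersection over union of two (x_min, y_min, x_max, y_max) boxes."""
    a, b = _box(a), _box(b)
    for box in (a, b):
        if box[2] <= box[0] or box[3] <= box[1]:
            raise ValueError(f"degenerate box {box.tolist()}")
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = (
        (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    )
    return inter / union


@dataclass
class MatchResult:
    """Per-detection TP/FP flags (score-descending order) and the FN count."""

    tp: np.ndarray  # bool, one per detection
    scores: np.ndarray  # matching order, descending
    n_ground_truth: int

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_ground_truth - self.n_tp

    def precision(self) -> float:
        n = len(self.tp)
        return self.n_tp / n if n else 0.0


def match_detections(detections, ground_truths, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy score-ordered matching of detections to ground-truth boxes."""
    scores = np.asarray([_score(d) for d in detections], dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    gt_boxes = [_box(g) for g in ground_truths]
    taken = np.zeros(len(gt_boxes), dtype=bool)
    tp = np.zeros(len(detections), dtype=bool)
    for rank, di in enumerate(order):
        box = _box(detections[di])
        best_iou, best_j = -1.0, -1
        for j, gt in enumerate(gt_boxes):
            if taken[j]:
                continue
            v = iou(box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            tp[rank] = True
    return MatchResult(tp=tp, scores=scores[order], n_ground_truth=len(gt_boxes))


RECALL_POINTS = np.linspace(0.0, 1.0, 101)


def average_precision_50(
    detections_per_image, ground_truths_per_image, iou_threshold: float = 0.5
) -> float:
    """101-point interpolated average precision at the given IoU threshold.

    Both arguments map image id -> list of detections / ground-truth boxes.
    Returns NaN when there are no ground truths anywhere (the metric is
    undefined there, and NaN is deliberately distinct from an AP of 0).
    """
    total_gt = sum(len(g) for g in ground_truths_per_image.values())
    if total_gt == 0:
        return float("nan")
    scores, flags = [], []
    for img_id, gts in ground_truths_per_image.items():
        dets = detections_per_image.get(img_id, [])
        m = match_detections(dets, gts, iou_threshold)
        scores.append(m.scores)
        flags.append(m.tp)
    scores = np.concatenate(scores) if scores else np.empty(0)
    flags = np.concatenate(flags) if flags else np.empty(0, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    tp_cum = np.cumsum(flags[order])
    fp_cum = np.cumsum(~flags[order])
    rec = tp_cum / total_gt
    prec = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # interpolated precision: running max from the right
    prec_i = np.maximum.accumulate(prec[::-1])[::-1] if len(prec) else prec
    ap = 0.0
    for r in RECALL_POINTS:
        mask = rec >= r
        ap += prec_i[mask].max() if mask.any() else 0.0
    return ap / len(RECALL_POINTS)


def recall(match: MatchResult) -> float:
    """TP / (TP + FN); undefined without ground truths."""
    if match.n_ground_truth == 0:
        raise ValueError("recall undefined with zero ground truths")
    return match.n_tp / match.n_ground_truth


def f1(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of two percentages, rounded half-up to one decimal."""
    precision_pct, recall_pct = float(precision_pct), float(recall_pct)
    for v in (precision_pct, recall_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percentage out of range: {v}")
    if precision_pct == 0.0 and recall_pct == 0.0:
        raise ValueError("F1 undefined for P = R = 0")
    value = 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# COCO JSON interfaces
# ---------------------------------------------------------------------------


def load_coco_ground_truth(path) -> dict:
    """Read a COCO detection ground-truth file -> {image_id: [corner boxes]}."""
    with open(path) as fh:
        payload = json.load(fh)
    out = {img["id"]: [] for img in payload["images"]}
    for ann in payload["annotations"]:
        x, y, w, h = ann["bbox"]
        out[ann["image_id"]].append((x, y, x + w, y + h))
    return out


def load_coco_detections(path) -> dict:
    """Read a COCO results file -> {image_id: [(x0, y0, x1, y1, score)]}."""
    with open(path) as fh:
        payload = json.load(fh)
    out: dict = {}
    for det in payload:
        x, y, w, h = det["bbox"]
        out.setdefault(det["image_id"], []).append(
            (x, y, x + w, y + h, det["score"])
        )
    return out
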