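"""Detection metrics: IoU, greedy matching, precision/recall, AP and mAP.

Boxes are ``(x1, y1, x2, y2)`` in 0-based continuous pixel coordinates with
exclusive right/bottom corners; areas are ``(x2-x1)*(y2-y1)``.  AP is the
area under the precision-recall curve after applying the monotone precision
envelope, integrated over all score cutoffs (the continuous variant); an
optional 101-point interpolation is provided for cross-tool comparability.
mAP50:95 averages mAP over IoU thresholds 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionRecord",
    "MatchResult",
    "APResult",
    "iou",
    "iou_matrix",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
]

IOU_GRID_50_95 = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class DetectionRecord:
    """One predicted or ground-truth box.  ``score`` is None for ground truth."""

    image_id: str
    class_id: int
    box: tuple  # (x1, y1, x2, y2)
    score: float | None = None

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box} (corners must be ordered, area > 0)")
        if self.class_id < 0:
            raise ValueError("class_id must be nonnegative")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class MatchResult:
    tp_flags: np.ndarray  # bool per detection, score-descending order
    fp_flags: np.ndarray
    fn_count: int
    matched_ious: list


@dataclass
class APResult:
    per_class_ap: dict  # class_id -> AP at IoU 0.5
    map50: float
    map50_95: float
    precision: float
    recall: float
    per_class_ap_50_95: dict = field(default_factory=dict)
    excluded_classes: list = field(default_factory=list)


def _validate_box(b) -> tuple:
    x1, y1, x2, y2 = (float(v) for v in b)
    if not (x2 > x1 and y2 > y1):
        raise ValueError(f"degenerate box {b}")
    return x1, y1, x2, y2


def iou(a, b) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ax1, ay1, ax2, ay2 = _validate_box(a)
    bx1, by1, bx2, by2 = _validate_box(b)
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (N,4) and (M,4) arrays of xyxy boxes."""
    a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 4)
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(union > 0, inter / union, 0.0)
    return m


def match_detections(dets, gts, iou_threshold: float) -> MatchResult:
    """Greedy one-to-one matching of detections to ground truths.

    Detections (one image, one class) are taken in descending score order
    (stable for ties); each claims the unmatched ground truth of highest IoU
    at or above the threshold.  Matched detections are TP, the rest FP;
    unmatched ground truths are FN.
    """
    n_det, n_gt = len(dets), len(gts)
    tp = np.zeros(n_det, dtype=bool)
    fp = np.zeros(n_det, dtype=bool)
    matched_ious: list = []
    if n_det == 0:
        return MatchResult(tp, fp, n_gt, matched_ious)
    order = sorted(range(n_det), key=lambda i: -dets[i].score)
    gt_taken = np.zeros(n_gt, dtype=bool)
    for rank, di in enumerate(order):
        best_iou, best_g = 0.0, -1
        for g in range(n_gt):
            if gt_taken[g]:
                continue
            v = iou(dets[di].box, gts[g].box)
            if v > best_iou:
                best_iou, best_g = v, g
        if best_g >= 0 and best_iou >= iou_threshold:
            gt_taken[best_g] = True
            tp[rank] = True
            matched_ious.append(best_iou)
        else:
            fp[rank] = True
    return MatchResult(tp, fp, int(n_gt - gt_taken.sum()), matched_ious)


def precision_recall(tp: int, fp: int, fn: int):
    """P = TP/(TP+FP), R = TP/(TP+FN); 0 when the denominator is 0."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    return p, r


def _ap_from_flags(tp_flags: np.ndarray, n_gt: int, interpolation: str) -> float:
    """AP from score-ordered TP flags via the enveloped PR curve."""
    if n_gt == 0:
        raise ValueError("AP undefined with zero ground truths")
    if tp_flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone non-increasing precision envelope
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    if interpolation == "all_points":
        idx = np.where(mrec[1:] != mrec[:-1])[0]
        return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    if interpolation == "101_point":
        grid = np.linspace(0.0, 1.0, 101)
        pre_at = np.array([mpre[np.searchsorted(mrec, r, side="left")] if r <= mrec[-1] else 0.0 for r in grid])
        return float(pre_at.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


def average_precision(dets, gts, iou_threshold: float, interpolation: str = "all_points") -> float:
    """AP for one class across images.

    Detections carry scores; matching is per image against that image's
    ground truths; the PR curve sweeps all score cutoffs (descending score,
    stable tie order).  Raises when the class has no ground truths.
    """
    if len(gts) == 0:
        raise ValueError("AP undefined for a class with no ground truths")
    by_image = defaultdict(list)
    for g in gts:
        by_image[g.image_id].append(g)
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    gt_taken = {img: np.zeros(len(v), dtype=bool) for img, v in by_image.items()}
    tp_flags = np.zeros(len(dets), dtype=bool)
    for rank, di in enumerate(order):
        d = dets[di]
        img_gts = by_image.get(d.image_id, [])
        best_iou, best_g = 0.0, -1
        for g, gt in enumerate(img_gts):
            if gt_taken[d.image_id][g]:
                continue
            v = iou(d.box, gt.box)
            if v > best_iou:
                best_iou, best_g = v, g
        if best_g >= 0 and best_iou >= iou_threshold:
            gt_taken[d.image_id][best_g] = True
            tp_flags[rank] = True
    return _ap_from_flags(tp_flags, len(gts), interpolation)


def mean_ap(per_class_ap: dict) -> float:
    """Unweighted arithmetic mean of per-class AP values."""
    if not per_class_ap:
        raise ValueError("mean AP undefined over an empty class map")
    return float(np.mean(list(per_class_ap.values())))


def evaluate_detections(
    dets,
    gts,
    num_classes: int | None = None,
    interpolation: str = "all_points",
    iou_thresholds=IOU_GRID_50_95,
) -> APResult:
    """Full metric stack: per-class AP at 0.5, mAP50, mAP50:95, P and R.

    Classes with zero ground truths are excluded from the class means (and
    listed in ``excluded_classes``) rather than scored 0.  Precision and
    recall are aggregate counts at IoU 0.5 over all classes, with every
    detection participating (score cutoff at 0, matching rule as above).
    """
    classes = sorted({g.class_id for g in gts} | {d.class_id for d in dets})
    if num_classes is not None:
        classes = list(range(num_classes))
    per_class_ap: dict = {}
    per_class_ap_grid: dict = {}
    excluded: list = []
    tp = fp = fn = 0
    for c in classes:
        c_dets = [d for d in dets if d.class_id == c]
        c_gts = [g for g in gts if g.class_id == c]
        if not c_gts:
            excluded.append(c)
            continue
        per_class_ap[c] = average_precision(c_dets, c_gts, 0.5, interpolation)
        per_class_ap_grid[c] = [
            average_precision(c_dets, c_gts, t, interpolation) for t in iou_thresholds
        ]
        by_img = defaultdict(lambda: ([], []))
        for d in c_dets:
            by_img[d.image_id][0].append(d)
        for g in c_gts:
            by_img[g.image_id][1].append(g)
        for img_dets, img_gts in by_img.values():
            m = match_detections(img_dets, img_gts, 0.5)
            tp += int(m.tp_flags.sum())
            fp += int(m.fp_flags.sum())
            fn += m.fn_count
    if not per_class_ap:
        raise ValueError("no class has ground truths; metrics undefined")
    p, r = precision_recall(tp, fp, fn)
    map50 = mean_ap(per_class_ap)
    map50_95 = float(np.mean([np.mean(v) for v in per_class_ap_grid.values()]))
    return APResult(
        per_class_ap=per_class_ap,
        map50=map50,
        map50_95=map50_95,
        precision=p,
        recall=r,
        per_class_ap_50_95={c: float(np.mean(v)) for c, v in per_class_ap_grid.items()},
        excluded_classes=excluded,
    )
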