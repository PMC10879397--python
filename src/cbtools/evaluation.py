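"""Object-detection evaluation: IoU, matching, precision/recall, AP, mAP.

Matching is per-image, per-class, greedy by descending confidence and
one-to-one: each detection takes the unmatched ground truth of highest
IoU provided it clears the threshold.  AP uses all-point (area under the
precision envelope) interpolation; mAP averages AP over the IoU ladder
0.50:0.95:0.05 and, for multi-class data, over classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .tiles import Box

__all__ = [
    "DEFAULT_IOU_LADDER",
    "MatchSet",
    "PRResult",
    "EvalResult",
    "iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_ap",
]

DEFAULT_IOU_LADDER: tuple[float, ...] = tuple(
    round(0.5 + 0.05 * k, 2) for k in range(10)
)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes in the same coordinate frame."""
    if a.w <= 0 or a.h <= 0 or b.w <= 0 or b.h <= 0:
        warnings.warn("zero-area box in IoU computation", stacklevel=2)
        return 0.0
    ax0, ay0, ax1, ay1 = a.corners()
    bx0, by0, bx1, by1 = b.corners()
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union


@dataclass(frozen=True)
class MatchSet:
    """Outcome of greedy matching at one IoU threshold.

    ``tp`` holds ``(detection_index, ground_truth_index)`` pairs, ``fp``
    the unmatched detection indices, ``fn`` the unmatched ground-truth
    indices.  ``order`` lists all detection indices in processed
    (descending-confidence) order.
    """

    tp: tuple[tuple[int, int], ...]
    fp: tuple[int, ...]
    fn: tuple[int, ...]
    iou_threshold: float
    order: tuple[int, ...]

    @property
    def tp_flags(self) -> list[bool]:
        """Per-detection TP flag in processed order."""
        tp_dets = {d for d, _ in self.tp}
        return [d in tp_dets for d in self.order]


def _confidence(b: Box) -> float:
    return 1.0 if b.confidence is None else b.confidence


def match_detections(
    dets: Sequence[Box], gts: Sequence[Box], iou_threshold: float = 0.5
) -> MatchSet:
    """Greedily match detections to ground truths, one-to-one.

    Detections are processed in descending confidence (ties broken by
    input order); each takes the unmatched ground truth with the highest
    IoU if that IoU is at or above the threshold, otherwise it is a false
    positive.  Leftover ground truths are false negatives.
    """
    order = sorted(range(len(dets)), key=lambda i: -_confidence(dets[i]))
    matched: set[int] = set()
    tp: list[tuple[int, int]] = []
    fp: list[int] = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if j in matched:
                continue
            val = iou(dets[i], gt)
            if val > best_iou:
                best_j, best_iou = j, val
        if best_j >= 0 and best_iou >= iou_threshold:
            matched.add(best_j)
            tp.append((i, best_j))
        else:
            fp.append(i)
    fn = tuple(j for j in range(len(gts)) if j not in matched)
    return MatchSet(tuple(tp), tuple(fp), fn, iou_threshold, tuple(order))


@dataclass(frozen=True)
class PRResult:
    """Cumulative PR curve plus the all-detections operating point."""

    points: tuple[tuple[float, float], ...]  # (recall, precision)
    precision: float
    recall: float
    recall_undefined: bool = False


def precision_recall(matchset: MatchSet, n_gt: int) -> PRResult:
    """Cumulative precision/recall over the confidence-sorted detections.

    With no ground truths and no detections both scalars are defined as 1;
    with detections but no ground truths recall is flagged undefined.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be non-negative")
    flags = matchset.tp_flags
    if not flags:
        if n_gt == 0:
            return PRResult((), 1.0, 1.0)
        return PRResult((), 1.0, 0.0)
    tp_cum = np.cumsum(flags)
    k = np.arange(1, len(flags) + 1)
    precisions = tp_cum / k
    if n_gt == 0:
        return PRResult(
            tuple((0.0, float(p)) for p in precisions),
            float(precisions[-1]),
            0.0,
            recall_undefined=True,
        )
    recalls = tp_cum / n_gt
    points = tuple((float(r), float(p)) for r, p in zip(recalls, precisions))
    return PRResult(points, float(precisions[-1]), float(recalls[-1]))


def _ap_from_flags(flags: Sequence[bool], n_gt: int) -> float:
    """All-point interpolated AP from per-detection TP flags (conf order)."""
    if n_gt == 0:
        return 1.0 if not flags else 0.0
    if not flags:
        return 0.0
    tp_cum = np.cumsum(flags)
    recalls = tp_cum / n_gt
    precisions = tp_cum / np.arange(1, len(flags) + 1)
    # precision envelope from the right, then sum Δrecall * envelope
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recalls, envelope):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def average_precision(
    dets: Sequence[Box], gts: Sequence[Box], iou_threshold: float = 0.5
) -> float:
    """Single-image, single-class AP at one IoU threshold."""
    ms = match_detections(dets, gts, iou_threshold)
    return _ap_from_flags(ms.tp_flags, len(gts))


@dataclass(frozen=True)
class EvalResult:
    """Metric bundle over the IoU ladder.

    ``pr_points`` is the pooled PR curve of class 0 at the lowest ladder
    threshold.  ``ap_per_threshold`` maps each IoU threshold to the
    class-averaged AP.
    """

    pr_points: tuple[tuple[float, float], ...]
    ap_per_threshold: dict[float, float]
    map50: float | None
    map_overall: float
    per_class_ap50: dict[int, float] = field(default_factory=dict)
    precision: float | None = None
    recall: float | None = None


def _as_image_map(
    boxes: Mapping[str, Sequence[Box]] | Sequence[Box],
) -> dict[str, list[Box]]:
    if isinstance(boxes, Mapping):
        return {k: list(v) for k, v in boxes.items()}
    return {"": list(boxes)}


def _pooled_flags(
    dets: dict[str, list[Box]],
    gts: dict[str, list[Box]],
    class_id: int,
    threshold: float,
) -> tuple[list[bool], int]:
    """Match per image, pool (confidence, flag) pairs across images."""
    pooled: list[tuple[float, int, bool]] = []
    n_gt = 0
    for rank, img in enumerate(sorted(set(dets) | set(gts))):
        d = [b for b in dets.get(img, []) if b.class_id == class_id]
        g = [b for b in gts.get(img, []) if b.class_id == class_id]
        n_gt += len(g)
        ms = match_detections(d, g, threshold)
        for idx, flag in zip(ms.order, ms.tp_flags):
            pooled.append((-_confidence(d[idx]), rank, flag))
    pooled.sort(key=lambda t: (t[0], t[1]))
    return [flag for _, _, flag in pooled], n_gt


def mean_ap(
    dets: Mapping[str, Sequence[Box]] | Sequence[Box],
    gts: Mapping[str, Sequence[Box]] | Sequence[Box],
    thresholds: Sequence[float] = DEFAULT_IOU_LADDER,
) -> EvalResult:
    """AP per IoU threshold, averaged over classes; mean over the ladder.

    ``dets``/``gts`` are either flat box lists (one image) or mappings
    from image identifier to box list.  Classes are those present in the
    ground truth; with a single class the per-threshold mAP equals that
    class's AP.
    """
    thresholds = list(thresholds)
    if not thresholds or any(
        b <= a for a, b in zip(thresholds, thresholds[1:])
    ):
        raise ValueError("thresholds must be non-empty and strictly increasing")
    det_map = _as_image_map(dets)
    gt_map = _as_image_map(gts)
    classes = sorted({b.class_id for boxes in gt_map.values() for b in boxes})
    if not classes:
        classes = sorted(
            {b.class_id for boxes in det_map.values() for b in boxes}
        ) or [0]

    ap_per_threshold: dict[float, float] = {}
    per_class_ap50: dict[int, float] = {}
    for t in thresholds:
        aps = []
        for c in classes:
            flags, n_gt = _pooled_flags(det_map, gt_map, c, t)
            ap = _ap_from_flags(flags, n_gt)
            aps.append(ap)
            if t == thresholds[0]:
                per_class_ap50[c] = ap
        ap_per_threshold[t] = float(np.mean(aps))

    pr_class = classes[0]
    flags, n_gt = _pooled_flags(det_map, gt_map, pr_class, thresholds[0])
    if flags:
        tp_cum = np.cumsum(flags)
        k = np.arange(1, len(flags) + 1)
        prec = tp_cum / k
        rec = tp_cum / n_gt if n_gt else np.zeros(len(flags))
        pr_points = tuple((float(r), float(p)) for r, p in zip(rec, prec))
        op_precision = float(prec[-1])
        op_recall = float(rec[-1]) if n_gt else None
    else:
        pr_points = ()
        op_precision = 1.0 if n_gt == 0 else None
        op_recall = 1.0 if n_gt == 0 else 0.0

    map50 = ap_per_threshold.get(0.5)
    return EvalResult(
        pr_points=pr_points,
        ap_per_threshold=ap_per_threshold,
        map50=map50,
        map_overall=float(np.mean(list(ap_per_threshold.values()))),
        per_class_ap50=per_class_ap50,
        precision=op_precision,
        recall=op_recall,
    )
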