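"""Hard-negative mining: harvest confident false positives as a second class.

False positives from a fixed detection set become explicit class-1
("non-CB") labels, filtered to resemble true CB boxes in size, capped so
negatives never outnumber the positives, and merged back into the label
set to form a two-class dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .evaluation import iou, match_detections
from .tiles import CB_CLASS, NON_CB_CLASS, Box

__all__ = ["MiningConfig", "mine_false_positives", "build_two_class_dataset"]


@dataclass(frozen=True)
class MiningConfig:
    """Rules for selecting hard negatives.

    ``cap_ratio`` bounds the global number of non-CB instances as a
    fraction of CB instances.  ``size_band`` is the percentile band of the
    ground-truth CB box widths/heights a negative must fall inside — the
    "shape similarity" control.
    """

    iou_threshold: float = 0.5
    cap_ratio: float = 1.0
    size_band: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if not (0 < self.iou_threshold < 1):
            raise ValueError("iou_threshold must lie in (0, 1)")
        if not (0 < self.cap_ratio <= 1):
            raise ValueError("cap_ratio must lie in (0, 1]")
        lo, hi = self.size_band
        if not (0 <= lo < hi <= 100):
            raise ValueError("size_band must be a valid percentile interval")


def _as_map(boxes) -> dict[str, list[Box]]:
    if isinstance(boxes, Mapping):
        return {k: list(v) for k, v in boxes.items()}
    return {"": list(boxes)}


def mine_false_positives(
    dets: Mapping[str, Sequence[Box]] | Sequence[Box],
    gts: Mapping[str, Sequence[Box]] | Sequence[Box],
    config: MiningConfig | None = None,
) -> dict[str, list[Box]]:
    """Select false-positive detections as class-1 negative labels.

    Detections unmatched to any class-0 ground truth at the config IoU
    threshold are candidates; they are filtered to the ground-truth size
    band, deduplicated against class-1 boxes already present in ``gts``
    (making mining idempotent against a fixed detection set), sorted by
    descending confidence, and capped globally at
    ``cap_ratio x (total CB instances) - existing negatives``.
    """
    config = config or MiningConfig()
    det_map = _as_map(dets)
    gt_map = _as_map(gts)

    cb_boxes = [
        b for boxes in gt_map.values() for b in boxes if b.class_id == CB_CLASS
    ]
    n_existing_neg = sum(
        b.class_id == NON_CB_CLASS for boxes in gt_map.values() for b in boxes
    )
    if not cb_boxes:
        return {}
    widths = np.array([b.w for b in cb_boxes])
    heights = np.array([b.h for b in cb_boxes])
    lo, hi = config.size_band
    w_lo, w_hi = np.percentile(widths, [lo, hi])
    h_lo, h_hi = np.percentile(heights, [lo, hi])

    candidates: list[tuple[float, str, int, Box]] = []
    for img in sorted(det_map):
        d = list(det_map[img])
        g = [b for b in gt_map.get(img, []) if b.class_id == CB_CLASS]
        existing = [b for b in gt_map.get(img, []) if b.class_id == NON_CB_CLASS]
        ms = match_detections(d, g, config.iou_threshold)
        for rank, i in enumerate(ms.fp):
            fp = d[i]
            if not (w_lo <= fp.w <= w_hi and h_lo <= fp.h <= h_hi):
                continue
            if any(iou(fp, e) >= config.iou_threshold for e in existing):
                continue  # already mined in a previous pass
            conf = 1.0 if fp.confidence is None else fp.confidence
            candidates.append((conf, img, rank, replace(fp, class_id=NON_CB_CLASS)))

    cap = int(np.floor(config.cap_ratio * len(cb_boxes))) - n_existing_neg
    if cap <= 0:
        return {}
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    mined: dict[str, list[Box]] = {}
    for _, img, _, box in candidates[:cap]:
        mined.setdefault(img, []).append(box)
    return mined


def build_two_class_dataset(
    labels: Mapping[str, Sequence[Box]],
    negatives: Mapping[str, Sequence[Box]],
    iou_threshold: float = 0.5,
) -> dict[str, list[Box]]:
    """Merge mined negatives into the label set, never touching CB boxes.

    A negative overlapping a class-0 ground truth of its image at IoU at
    or above ``iou_threshold`` contradicts its false-positive status and
    is dropped with a warning.  Negative confidences are stripped: the
    output is a ground-truth label set.
    """
    out: dict[str, list[Box]] = {
        img: list(boxes) for img, boxes in labels.items()
    }
    for img, negs in negatives.items():
        cb = [b for b in out.get(img, []) if b.class_id == CB_CLASS]
        for neg in negs:
            if neg.class_id != NON_CB_CLASS:
                raise ValueError("negatives must all carry class_id 1")
            if any(iou(neg, b) >= iou_threshold for b in cb):
                warnings.warn(
                    f"image {img!r}: dropping negative overlapping a CB ground "
                    f"truth at IoU >= {iou_threshold}",
                    stacklevel=2,
                )
                continue
            out.setdefault(img, []).append(neg.without_confidence())
    return out
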