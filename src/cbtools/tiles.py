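"""Patch tiling, YOLO-dialect label I/O, dataset splitting and accounting.

The on-disk layout follows the de-facto YOLO convention: ``images/x.png``
pairs with ``labels/x.txt`` by shared basename, one box per line in the
dialect ``class cx cy w h [conf]`` with coordinates normalized to the image
size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Patch",
    "Box",
    "DatasetSplit",
    "tile_image",
    "read_yolo_labels",
    "write_yolo_labels",
    "split_dataset",
    "dataset_stats",
    "box_size_summary",
]

CB_CLASS = 0
NON_CB_CLASS = 1


@dataclass(frozen=True)
class Patch:
    """An RGB raster together with its position in the source image.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3), uint8
        The patch raster.
    origin_xy : (int, int)
        0-based pixel offset ``(x, y)`` of the top-left corner in the
        source image.
    um_per_px : float
        Physical resolution in microns per pixel.
    """

    pixels: np.ndarray
    origin_xy: tuple[int, int] = (0, 0)
    um_per_px: float = 0.12

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 raster, got shape {px.shape}")
        if px.shape[0] <= 0 or px.shape[1] <= 0:
            raise ValueError("patch must be non-empty")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.origin_xy[0] < 0 or self.origin_xy[1] < 0:
            raise ValueError("origin components must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class Box:
    """One bounding box in normalized YOLO convention (center + size).

    ``class_id`` 0 denotes a CB, 1 a mined non-CB.  ``confidence`` is
    ``None`` for ground-truth boxes.
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"center ({self.cx}, {self.cy}) outside [0, 1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"size ({self.w}, {self.h}) outside (0, 1]")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def corners(self) -> tuple[float, float, float, float]:
        """Return ``(x0, y0, x1, y1)`` in normalized coordinates."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )

    def to_pixels(self, width: int, height: int) -> tuple[float, float, float, float]:
        x0, y0, x1, y1 = self.corners()
        return (x0 * width, y0 * height, x1 * width, y1 * height)

    def without_confidence(self) -> "Box":
        return replace(self, confidence=None)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validate/test identifier lists covering a dataset."""

    train: tuple[str, ...]
    validate: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validate), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split partitions are not pairwise disjoint")

    @property
    def all_ids(self) -> frozenset[str]:
        return frozenset(self.train) | frozenset(self.validate) | frozenset(self.test)


def tile_image(
    image: np.ndarray, tile_size: int = 512, um_per_px: float = 0.12
) -> list[Patch]:
    """Cut ``image`` into non-overlapping ``tile_size``-square patches.

    Tiles are laid on a regular grid from the top-left corner with stride
    equal to ``tile_size``; partial tiles at the right/bottom edges are
    dropped.  An image smaller than ``tile_size`` in either dimension
    yields an empty list.
    """
    if tile_size < 32:
        raise ValueError("tile_size must be at least 32 px")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {image.shape}")
    h, w = image.shape[:2]
    tiles: list[Patch] = []
    for y in range(0, h - tile_size + 1, tile_size):
        for x in range(0, w - tile_size + 1, tile_size):
            tiles.append(
                Patch(
                    pixels=image[y : y + tile_size, x : x + tile_size].copy(),
                    origin_xy=(x, y),
                    um_per_px=um_per_px,
                )
            )
    return tiles


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream


def read_yolo_labels(
    stream: str | IO[str] | Iterable[str], has_confidence: bool = False
) -> list[Box]:
    """Parse YOLO-dialect label text into :class:`Box` objects.

    Each non-blank line must read ``class cx cy w h`` (plus a trailing
    confidence when ``has_confidence``).  Malformed or out-of-range lines
    are rejected with a warning naming the line number; valid lines are
    returned in input order.
    """
    n_fields = 6 if has_confidence else 5
    boxes: list[Box] = []
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != n_fields:
            warnings.warn(
                f"line {lineno}: expected {n_fields} fields, got {len(parts)}; "
                "line rejected",
                stacklevel=2,
            )
            continue
        try:
            class_id = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if has_confidence else None
            boxes.append(Box(class_id, cx, cy, w, h, conf))
        except ValueError as exc:
            warnings.warn(f"line {lineno}: {exc}; line rejected", stacklevel=2)
    return boxes


def write_yolo_labels(boxes: Sequence[Box]) -> str:
    """Serialize boxes to YOLO label text, 6-decimal fixed formatting."""
    lines = []
    for b in boxes:
        fields = [str(b.class_id)] + [f"{v:.6f}" for v in (b.cx, b.cy, b.w, b.h)]
        if b.confidence is not None:
            fields.append(f"{b.confidence:.6f}")
        lines.append(" ".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def _ceil_frac(frac: float, n: int) -> int:
    # Exact rational arithmetic: ceil(0.05 * 100) must be 5, not 6, despite
    # 0.05 having no exact binary representation.
    return math.ceil(Fraction(frac).limit_denominator(10**9) * n)


def split_dataset(
    ids: Sequence[str],
    test_frac: float = 0.05,
    train_frac_of_rest: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Partition identifiers into train/validate/test by seeded shuffle.

    Sizes follow the ceiling convention: ``|test| = ceil(test_frac * n)``,
    ``|validate| = ceil((1 - train_frac_of_rest) * (n - |test|))`` and the
    training set takes the remainder.  Membership is a permutation-invariant
    function of ``(set(ids), seed)``.
    """
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must lie in (0, 1)")
    if not (0 < train_frac_of_rest < 1):
        raise ValueError("train_frac_of_rest must lie in (0, 1)")
    ordered = sorted(str(i) for i in ids)
    n = len(ordered)
    if len(set(ordered)) != n:
        raise ValueError("ids must be unique")
    if n < 3:
        raise ValueError(f"need at least 3 ids to form three partitions, got {n}")
    n_test = _ceil_frac(test_frac, n)
    rest = n - n_test
    n_val = _ceil_frac(1 - train_frac_of_rest, rest)
    n_train = rest - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"degenerate partition sizes (train={n_train}, val={n_val}, test={n_test})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [ordered[i] for i in perm]
    return DatasetSplit(
        train=tuple(shuffled[n_test + n_val :]),
        validate=tuple(shuffled[n_test : n_test + n_val]),
        test=tuple(shuffled[:n_test]),
    )


def dataset_stats(
    labels_by_partition: Mapping[str, Mapping[str, Sequence[Box]]],
    images_by_partition: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Tabulate per-partition image and label counts.

    Parameters
    ----------
    labels_by_partition : mapping
        ``{partition: {image_id: [Box, ...]}}``.
    images_by_partition : mapping, optional
        ``{partition: [image_id, ...]}``; defaults to the label keys.  A
        label file referencing an image missing from this listing raises a
        warning.

    Returns
    -------
    DataFrame indexed by partition (plus a ``total`` row) with columns
    ``images``, ``cb_labels``, ``non_cb_labels``.
    """
    rows = {}
    for part, labels in labels_by_partition.items():
        if images_by_partition is not None:
            image_ids = list(images_by_partition.get(part, []))
            missing = sorted(set(labels) - set(image_ids))
            if missing:
                warnings.warn(
                    f"partition {part!r}: label files reference missing images "
                    f"{missing}",
                    stacklevel=2,
                )
        else:
            image_ids = list(labels)
        boxes = [b for img_boxes in labels.values() for b in img_boxes]
        rows[part] = {
            "images": len(image_ids),
            "cb_labels": sum(b.class_id == CB_CLASS for b in boxes),
            "non_cb_labels": sum(b.class_id == NON_CB_CLASS for b in boxes),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    table.loc["total"] = table.sum(axis=0)
    return table


def box_size_summary(boxes: Sequence[Box]) -> pd.DataFrame:
    """Summarize normalized box widths/heights (min, quartiles, mean, max)."""
    if not boxes:
        return pd.DataFrame(
            index=["min", "q25", "median", "q75", "max", "mean"],
            columns=["width", "height"],
            dtype=float,
        )
    w = np.array([b.w for b in boxes])
    h = np.array([b.h for b in boxes])
    stats = {
        "width": [w.min(), *np.percentile(w, [25, 50, 75]), w.max(), w.mean()],
        "height": [h.min(), *np.percentile(h, [25, 50, 75]), h.max(), h.mean()],
    }
    return pd.DataFrame(stats, index=["min", "q25", "median", "q75", "max", "mean"])
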