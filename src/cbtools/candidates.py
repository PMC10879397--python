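"""Candidate centroblast detection from classical segmentation.

Cells are segmented by Otsu thresholding plus a small morphological
opening (a stand-in for any external nucleus segmenter; precomputed label
masks are accepted through the same contract), then filtered by equivalent
circular diameter in microns and by the aspect ratio of the minimum-area
rotated bounding rectangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import disk, opening

from .preprocess import luminance, otsu_binarize
from .tiles import Box, Patch

__all__ = [
    "CellContour",
    "CandidateCriteria",
    "Verdict",
    "segment_cells",
    "equivalent_diameter_um",
    "aspect_ratio",
    "filter_candidates",
    "baseline_detect",
]


@dataclass(frozen=True)
class CellContour:
    """A closed cell outline with derived geometry.

    ``polygon`` is an (N, 2) array of (x, y) pixel coordinates.
    ``axis_lengths`` are the two side lengths of the fitted rotated
    bounding rectangle, in the order the fit returns them (not sorted).
    ``bbox`` is the axis-aligned ``(x0, y0, x1, y1)`` rectangle with
    half-open pixel extents.
    """

    polygon: np.ndarray
    area_px2: float
    axis_lengths: tuple[float, float]
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.area_px2 < 0:
            raise ValueError("area must be non-negative")

    @property
    def is_degenerate(self) -> bool:
        return min(self.axis_lengths) <= 0


@dataclass(frozen=True)
class CandidateCriteria:
    """Geometric thresholds for keeping a contour as a candidate CB."""

    min_equiv_diameter_um: float = 5.13
    aspect_ratio_range: tuple[float, float] = (0.7, 1.3)
    um_per_px: float = 0.12

    def __post_init__(self) -> None:
        if self.min_equiv_diameter_um <= 0:
            raise ValueError("min_equiv_diameter_um must be positive")
        lo, hi = self.aspect_ratio_range
        if not (0 < lo < hi):
            raise ValueError("aspect_ratio_range must satisfy 0 < lo < hi")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")


@dataclass(frozen=True)
class Verdict:
    """Per-contour filter outcome with the failing test recorded."""

    kept: bool
    equiv_diameter_um: float
    aspect_ratio: float | None
    reason: str  # "ok" | "diameter" | "aspect_ratio" | "degenerate"


def _fit_rotated_rect(points_xy: np.ndarray) -> tuple[float, float]:
    """Side lengths of the minimum-area rotated rectangle, fit order."""
    rect = MultiPoint([tuple(p) for p in points_xy]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        return (0.0, 0.0)
    coords = np.asarray(rect.exterior.coords)
    side_a = float(np.hypot(*(coords[1] - coords[0])))
    side_b = float(np.hypot(*(coords[2] - coords[1])))
    return (side_a, side_b)


def _contour_from_region(region) -> CellContour:
    # find_contours wants a float image; pad so border-touching regions
    # still produce closed outlines.
    padded = np.pad(region.image.astype(float), 1)
    outlines = find_contours(padded, 0.5)
    r0, c0, r1, c1 = region.bbox
    if outlines:
        longest = max(outlines, key=len)
        # rows/cols in padded frame -> (x, y) in image frame
        poly = np.column_stack(
            [longest[:, 1] - 1 + c0, longest[:, 0] - 1 + r0]
        )
    else:  # pragma: no cover - single-pixel regions always outline
        poly = np.array([[c0, r0]], dtype=float)
    axes = _fit_rotated_rect(poly)
    return CellContour(
        polygon=poly,
        area_px2=float(region.area),
        axis_lengths=axes,
        bbox=(c0, r0, c1, r1),
    )


def segment_cells(
    patch: Patch,
    labels: np.ndarray | None = None,
    opening_radius: int = 2,
) -> list[CellContour]:
    """Segment dark cells and return their external contours.

    Without ``labels``: Otsu foreground on the luminance channel, a
    morphological opening of ``opening_radius`` to suppress tiny noise,
    then connected components.  With ``labels`` (an integer label mask of
    the same height/width), thresholding is skipped and each labeled
    region becomes one contour — the pass-through contract for external
    segmenters.
    """
    if labels is None:
        gray = luminance(patch.pixels)
        mask, threshold = otsu_binarize(gray)
        if threshold is None:
            return []
        if opening_radius > 0:
            mask = opening(mask, disk(opening_radius))
        labels = label(mask, connectivity=2)
    else:
        labels = np.asarray(labels)
        if labels.shape != patch.pixels.shape[:2]:
            raise ValueError("label mask shape does not match patch")
    return [_contour_from_region(r) for r in regionprops(labels)]


def equivalent_diameter_um(area_px2: float, um_per_px: float = 0.12) -> float:
    """Diameter (μm) of the circle with the same area as the contour."""
    if area_px2 < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * math.sqrt(area_px2 / math.pi) * um_per_px


def aspect_ratio(contour: CellContour) -> float:
    """Ratio of the fitted rectangle's first axis to its second.

    The order is as fitted, not sorted, so values both below and above 1
    occur; the symmetric acceptance band makes the filter decision
    independent of the order.
    """
    a, b = contour.axis_lengths
    if a <= 0 or b <= 0:
        raise ValueError("degenerate contour: zero-length axis")
    return a / b


def filter_candidates(
    contours: list[CellContour], criteria: CandidateCriteria | None = None
) -> tuple[list[CellContour], list[Verdict]]:
    """Keep contours passing the diameter and aspect-ratio tests.

    Returns the kept subset and a verdict per input contour recording the
    measured quantities and which test failed.
    """
    criteria = criteria or CandidateCriteria()
    lo, hi = criteria.aspect_ratio_range
    kept: list[CellContour] = []
    verdicts: list[Verdict] = []
    for c in contours:
        d = equivalent_diameter_um(c.area_px2, criteria.um_per_px)
        if c.is_degenerate:
            verdicts.append(Verdict(False, d, None, "degenerate"))
            continue
        ar = aspect_ratio(c)
        if d < criteria.min_equiv_diameter_um:
            verdicts.append(Verdict(False, d, ar, "diameter"))
        elif not (lo <= ar <= hi):
            verdicts.append(Verdict(False, d, ar, "aspect_ratio"))
        else:
            kept.append(c)
            verdicts.append(Verdict(True, d, ar, "ok"))
    return kept, verdicts


def detection_confidence(
    equiv_diameter_um_value: float, criteria: CandidateCriteria
) -> float:
    """Monotone confidence in [0, 1]; 0.5 exactly at the diameter threshold."""
    return min(
        max(equiv_diameter_um_value / (2.0 * criteria.min_equiv_diameter_um), 0.0),
        1.0,
    )


def baseline_detect(
    patch: Patch,
    criteria: CandidateCriteria | None = None,
    labels: np.ndarray | None = None,
    opening_radius: int = 2,
) -> list[Box]:
    """Classical stand-in detector: segment, filter, emit one box per cell.

    Boxes are axis-aligned bounding rectangles of the kept contours,
    normalized to the patch size, class 0, with confidence monotone in the
    equivalent diameter.
    """
    criteria = criteria or CandidateCriteria(um_per_px=patch.um_per_px)
    contours = segment_cells(patch, labels=labels, opening_radius=opening_radius)
    kept, _ = filter_candidates(contours, criteria)
    h, w = patch.height, patch.width
    boxes: list[Box] = []
    for c in kept:
        x0, y0, x1, y1 = c.bbox
        d = equivalent_diameter_um(c.area_px2, criteria.um_per_px)
        boxes.append(
            Box(
                class_id=0,
                cx=(x0 + x1) / 2 / w,
                cy=(y0 + y1) / 2 / h,
                w=(x1 - x0) / w,
                h=(y1 - y0) / h,
                confidence=detection_confidence(d, criteria),
            )
        )
    return boxes
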