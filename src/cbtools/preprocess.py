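"""Background removal for stained tissue patches.

The pipeline separates dark cell bodies from the light background:
luminance histogram equalization, grayscale conversion, Otsu thresholding,
contour bookkeeping, dilation, small-contour fill-in, and finally a masked
copy of the original patch with everything outside the mask painted white.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk

from .tiles import Patch

__all__ = [
    "PreprocessConfig",
    "equalize_histogram",
    "otsu_binarize",
    "otsu_threshold",
    "remove_background",
    "luminance",
]

logger = logging.getLogger(__name__)

# Rec. 601 luma weights; coefficients sum to 1 so gray of a flat image is
# the flat value itself.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def luminance(rgb: np.ndarray) -> np.ndarray:
    """8-bit luminance of an 8-bit RGB raster."""
    rgb = np.asarray(rgb)
    y = rgb[..., :3].astype(np.float64) @ _LUMA_WEIGHTS
    return np.clip(np.round(y), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for :func:`remove_background`.

    ``fill_ratio`` is the fraction of the average bounding-rectangle area
    below which a contour is filled solid.  ``degenerate_policy`` governs
    behavior when Otsu is undefined (single-valued histogram): ``"passthrough"``
    returns the input unchanged, ``"empty"`` treats everything as background.
    """

    dilation_radius: int = 2
    fill_ratio: float = 0.5
    degenerate_policy: str = "passthrough"

    def __post_init__(self) -> None:
        if self.dilation_radius < 1:
            raise ValueError("dilation_radius must be >= 1")
        if not (0 < self.fill_ratio < 1):
            raise ValueError("fill_ratio must lie in (0, 1)")
        if self.degenerate_policy not in ("passthrough", "empty"):
            raise ValueError(f"unknown degenerate_policy {self.degenerate_policy!r}")


def _luminance_mapping(luma: np.ndarray) -> np.ndarray | None:
    """256-entry equalization lookup table, or None when degenerate."""
    hist = np.bincount(luma.ravel(), minlength=256)
    if np.count_nonzero(hist) <= 1:
        return None
    cdf = np.cumsum(hist) / luma.size
    return np.round(cdf * 255.0)


def equalize_histogram(patch: Patch) -> Patch:
    """Equalize the luminance histogram, preserving chromaticity.

    The monotone non-decreasing CDF mapping is computed on the luminance
    channel and applied as a per-pixel multiplicative gain on all three RGB
    channels, so hue and saturation ratios are untouched.  A degenerate
    (single-valued) histogram returns the input unchanged.
    """
    luma = luminance(patch.pixels)
    mapping = _luminance_mapping(luma)
    if mapping is None:
        return replace(patch, pixels=patch.pixels.copy())
    gain = mapping[luma] / np.maximum(luma, 1)
    out = np.clip(
        np.round(patch.pixels.astype(np.float64) * gain[..., None]), 0, 255
    ).astype(np.uint8)
    return replace(patch, pixels=out)


def otsu_threshold(gray: np.ndarray) -> int | None:
    """Integer threshold maximizing between-class variance, or None.

    Returns the smallest maximizing threshold ``t`` such that pixels
    ``<= t`` form the dark class; ``None`` when the histogram has a single
    occupied level.
    """
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        raise ValueError("expected 8-bit grayscale input")
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) <= 1:
        return None
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    mu0_sum = np.cumsum(hist * levels)
    mu_total = mu0_sum[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(256)
    sigma_b[valid] = (mu_total * w0[valid] - total * mu0_sum[valid]) ** 2 / (
        total**2 * w0[valid] * w1[valid]
    )
    return int(np.argmax(sigma_b))


def otsu_binarize(
    gray: np.ndarray, degenerate_policy: str = "empty"
) -> tuple[np.ndarray, int | None]:
    """Binarize 8-bit grayscale with Otsu's method, dark pixels foreground.

    Returns ``(mask, threshold)``.  When the histogram is single-valued the
    threshold is ``None`` and the mask follows ``degenerate_policy``
    (``"empty"`` → all background, ``"full"`` → all foreground).
    """
    gray = np.asarray(gray)
    t = otsu_threshold(gray)
    if t is None:
        if degenerate_policy == "full":
            return np.ones(gray.shape, dtype=bool), None
        return np.zeros(gray.shape, dtype=bool), None
    return gray <= t, t


def remove_background(
    patch: Patch, config: PreprocessConfig | None = None
) -> Patch:
    """Paint non-cell background white, keeping original cell pixels.

    Steps: equalize → grayscale → Otsu mask (dark foreground) → contour
    detection → average bounding-rectangle area → mask dilation → solid
    fill of contours smaller than ``fill_ratio`` of that average → copy of
    the *original* patch with unselected pixels set to (255, 255, 255).

    A degenerate Otsu (flat patch) returns the input unchanged and logs.
    """
    config = config or PreprocessConfig()
    equalized = equalize_histogram(patch)
    gray = luminance(equalized.pixels)
    mask, threshold = otsu_binarize(gray)
    if threshold is None:
        if config.degenerate_policy == "passthrough":
            logger.info("degenerate histogram; returning patch unchanged")
            return replace(patch, pixels=patch.pixels.copy())
        return replace(patch, pixels=np.full_like(patch.pixels, 255))

    labeled = label(mask, connectivity=2)
    regions = regionprops(labeled)
    selected = dilation(mask, disk(config.dilation_radius))
    if regions:
        bbox_areas = [
            (r.bbox[2] - r.bbox[0]) * (r.bbox[3] - r.bbox[1]) for r in regions
        ]
        avg_area = float(np.mean(bbox_areas))
        for r in regions:
            if r.area < config.fill_ratio * avg_area:
                rr0, cc0, rr1, cc1 = r.bbox
                filled = ndimage.binary_fill_holes(r.image)
                selected[rr0:rr1, cc0:cc1] |= filled

    out = np.where(selected[..., None], patch.pixels, np.uint8(255))
    return replace(patch, pixels=out.astype(np.uint8))


def mean_color_whiteout(patch: Patch) -> Patch:
    """Alternative background mode: pixels lighter than the image mean → white.

    A pixel whose luminance exceeds the mean luminance of the whole patch is
    replaced with (255, 255, 255); all other pixels keep their original
    values.
    """
    luma = luminance(patch.pixels)
    keep = luma <= luma.mean()
    out = np.where(keep[..., None], patch.pixels, np.uint8(255))
    return replace(patch, pixels=out.astype(np.uint8))
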