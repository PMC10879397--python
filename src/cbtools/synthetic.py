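"""Synthetic H&E-like patch generator with exact ground-truth boxes.

Scenes are filled ellipses ("cells") in a stain palette on a textured
light background.  Two stain modes mimic fresh (purple) and faded (pink)
slides.  Every class-0 annotation is exactly the bounding box of the
rasterized ellipse, so closed-loop tests of segmentation, filtering and
evaluation need no stored imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .tiles import Box, Patch

__all__ = [
    "SceneSpec",
    "PerturbSpec",
    "CellRecord",
    "PALETTES",
    "generate_patch",
    "perturb_detections",
]

# RGB anchors per stain mode; cells must be clearly darker than background
# so thresholding is well posed.
PALETTES: dict[str, dict[str, tuple[int, int, int]]] = {
    "purple": {"background": (231, 226, 236), "cell": (94, 58, 122)},
    "pink": {"background": (244, 228, 231), "cell": (205, 110, 138)},
}


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic patch.

    CB-like cells are large and round; clutter cells are either small
    round ("small" mode) or large elongated ("elongated" mode), both of
    which the candidate filter must reject.
    """

    n_cb: int = 5
    n_other: int = 0
    stain_mode: str = "purple"
    cb_diameter_um: tuple[float, float] = (7.0, 10.0)
    cb_aspect: tuple[float, float] = (0.9, 1.1)
    other_diameter_um: tuple[float, float] = (2.5, 4.0)
    other_elongated_diameter_um: tuple[float, float] = (5.6, 7.0)
    other_elongated_aspect: tuple[float, float] = (2.0, 3.0)
    image_size: int = 512
    um_per_px: float = 0.12
    noise_sd: float = 0.0
    texture_amp: float = 0.02
    overlap_allowed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cb < 0 or self.n_other < 0:
            raise ValueError("cell counts must be non-negative")
        if self.stain_mode not in PALETTES:
            raise ValueError(f"unknown stain_mode {self.stain_mode!r}")
        for rng_ in (self.cb_diameter_um, self.other_diameter_um):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("diameter ranges must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CellRecord:
    """Generator-side truth about one rendered cell."""

    kind: str  # "cb" | "small" | "elongated"
    center_rc: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    diameter_um: float
    aspect: float
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open pixels


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency multiplicative texture over the palette background."""
    size = spec.image_size
    base = np.array(PALETTES[spec.stain_mode]["background"], dtype=np.float64)
    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    fld = ndimage.zoom(coarse, size / 8, order=3)
    fld = 1.0 + spec.texture_amp * fld / max(np.abs(fld).max(), 1e-9)
    return base[None, None, :] * fld[:, :, None]


def _place(
    rng: np.random.Generator,
    size: int,
    margin: float,
    placed: list[tuple[float, float, float]],
    min_gap: float,
    allow_overlap: bool,
    retries: int = 2000,
) -> tuple[float, float]:
    lo, hi = margin, size - margin
    if hi <= lo:
        raise ValueError("cell too large for the image")
    for _ in range(retries):
        r = rng.uniform(lo, hi)
        c = rng.uniform(lo, hi)
        if allow_overlap or all(
            math.hypot(r - pr, c - pc) >= prad + min_gap
            for pr, pc, prad in placed
        ):
            return r, c
    raise _PlacementFailure


class _PlacementFailure(RuntimeError):
    pass


def generate_patch(
    spec: SceneSpec, return_cells: bool = False
) -> tuple[Patch, list[Box]] | tuple[Patch, list[Box], list[CellRecord]]:
    """Render one synthetic patch with exact class-0 annotations.

    Identical specs produce byte-identical patches and annotations.  Only
    CB-like cells are annotated; clutter is rendered but unlabeled.  With
    ``overlap_allowed=False`` cells keep a clear gap; infeasible packings
    raise ``RuntimeError`` after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)
    size = spec.image_size
    cell_base = np.array(PALETTES[spec.stain_mode]["cell"], dtype=np.float64)

    plan: list[str] = ["cb"] * spec.n_cb
    for _ in range(spec.n_other):
        plan.append("small" if rng.uniform() < 0.5 else "elongated")

    # Geometry first (with whole-scene restarts when a greedy placement
    # paints itself into a corner), rendering second.
    geometry: list[tuple[str, float, float, float, float, float, float, float]] = []
    for attempt in range(25):
        placed: list[tuple[float, float, float]] = []
        geometry.clear()
        try:
            for kind in plan:
                if kind == "cb":
                    d_um = rng.uniform(*spec.cb_diameter_um)
                    aspect = rng.uniform(*spec.cb_aspect)
                elif kind == "small":
                    d_um = rng.uniform(*spec.other_diameter_um)
                    aspect = rng.uniform(*spec.cb_aspect)
                else:  # elongated clutter: above the diameter cut but stretched
                    d_um = rng.uniform(*spec.other_elongated_diameter_um)
                    aspect = rng.uniform(*spec.other_elongated_aspect)
                d_px = d_um / spec.um_per_px
                # semi-axes preserving the equivalent diameter: a*b = (d/2)^2
                a = (d_px / 2.0) * math.sqrt(aspect)
                b = (d_px / 2.0) / math.sqrt(aspect)
                rot = rng.uniform(0.0, math.pi)
                reach = max(a, b)
                r0, c0 = _place(
                    rng,
                    size,
                    margin=reach + 3.0,
                    placed=placed,
                    min_gap=reach + 4.0,
                    allow_overlap=spec.overlap_allowed,
                )
                placed.append((r0, c0, reach))
                geometry.append((kind, r0, c0, a, b, rot, d_um, aspect))
            break
        except _PlacementFailure:
            continue
    else:
        raise RuntimeError(
            "could not place all cells without overlap; scene too crowded"
        )

    cells: list[CellRecord] = []
    boxes: list[Box] = []
    for kind, r0, c0, a, b, rot, d_um, aspect in geometry:
        rr, cc = draw_ellipse(r0, c0, a, b, shape=(size, size), rotation=rot)
        shade = cell_base + rng.normal(0.0, 3.0, size=3)
        img[rr, cc] = shade[None, :]
        bbox = (int(cc.min()), int(rr.min()), int(cc.max()) + 1, int(rr.max()) + 1)
        cells.append(
            CellRecord(kind, (r0, c0), (a, b), rot, d_um, aspect, bbox)
        )
        if kind == "cb":
            x0, y0, x1, y1 = bbox
            boxes.append(
                Box(
                    class_id=0,
                    cx=(x0 + x1) / 2 / size,
                    cy=(y0 + y1) / 2 / size,
                    w=(x1 - x0) / size,
                    h=(y1 - y0) / size,
                )
            )

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    patch = Patch(pixels=pixels, um_per_px=spec.um_per_px)
    if return_cells:
        return patch, boxes, cells
    return patch, boxes


@dataclass(frozen=True)
class PerturbSpec:
    """Noise model turning ground truth into simulated detections.

    ``conf_model`` is ``("constant", v)`` or ``("uniform", lo, hi)``.
    ``fp_rate`` is the Poisson mean of spurious boxes added per image;
    spurious boxes are rejection-sampled away from the ground truth so
    they stay false positives.
    """

    miss_rate: float = 0.0
    fp_rate: float = 0.0
    jitter_sd: float = 0.0  # px, applied to center and size
    conf_model: tuple = ("uniform", 0.5, 1.0)
    image_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.miss_rate <= 1):
            raise ValueError("miss_rate must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")
        if self.conf_model[0] not in ("constant", "uniform"):
            raise ValueError(f"unknown conf_model {self.conf_model!r}")


def _sample_conf(spec: PerturbSpec, rng: np.random.Generator) -> float:
    if spec.conf_model[0] == "constant":
        return float(spec.conf_model[1])
    return float(rng.uniform(spec.conf_model[1], spec.conf_model[2]))


def _clip01(v: float, lo: float = 0.0, hi: float = 1.0) -> float:
    return min(max(v, lo), hi)


def perturb_detections(
    gts: Sequence[Box], spec: PerturbSpec
) -> list[Box]:
    """Simulate a detector: drop, jitter and add spurious boxes, seeded."""
    rng = np.random.default_rng(spec.seed)
    scale = 1.0 / spec.image_size
    dets: list[Box] = []
    for b in gts:
        if rng.uniform() < spec.miss_rate:
            continue
        if spec.jitter_sd > 0:
            jc = rng.normal(0.0, spec.jitter_sd, size=4) * scale
        else:
            jc = np.zeros(4)
        dets.append(
            Box(
                class_id=b.class_id,
                cx=_clip01(b.cx + jc[0]),
                cy=_clip01(b.cy + jc[1]),
                w=_clip01(b.w + jc[2], lo=2 * scale),
                h=_clip01(b.h + jc[3], lo=2 * scale),
                confidence=_sample_conf(spec, rng),
            )
        )

    sizes = [(b.w, b.h) for b in gts] or [(0.05, 0.05)]
    from .evaluation import iou  # local import avoids a cycle at module load

    n_fp = int(rng.poisson(spec.fp_rate))
    for _ in range(n_fp):
        for _attempt in range(100):
            w, h = sizes[int(rng.integers(len(sizes)))]
            cand = Box(
                class_id=0,
                cx=float(rng.uniform(w / 2, 1 - w / 2)),
                cy=float(rng.uniform(h / 2, 1 - h / 2)),
                w=w,
                h=h,
                confidence=_sample_conf(spec, rng),
            )
            if all(iou(cand, g) < 0.1 for g in gts):
                dets.append(cand)
                break
    return dets
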