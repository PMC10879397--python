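"""Directory-level I/O for the {images/, labels/, predictions/} layout."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .tiles import Box, read_yolo_labels, write_yolo_labels

__all__ = [
    "IMAGE_EXTENSIONS",
    "load_image",
    "save_image",
    "list_images",
    "read_labels_dir",
    "write_labels_dir",
]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as an HxWx3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def list_images(directory: str | Path) -> dict[str, Path]:
    """Map image basename (stem) to path, sorted by stem."""
    directory = Path(directory)
    found = {
        p.stem: p
        for p in sorted(directory.iterdir())
        if p.suffix.lower() in IMAGE_EXTENSIONS
    }
    return dict(sorted(found.items()))


def read_labels_dir(
    directory: str | Path, has_confidence: bool = False
) -> dict[str, list[Box]]:
    """Read every ``*.txt`` label file in a directory, keyed by stem."""
    directory = Path(directory)
    out: dict[str, list[Box]] = {}
    for p in sorted(directory.glob("*.txt")):
        out[p.stem] = read_yolo_labels(p.read_text(), has_confidence=has_confidence)
    return out


def write_labels_dir(
    labels: Mapping[str, Sequence[Box]], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for stem, boxes in sorted(labels.items()):
        (directory / f"{stem}.txt").write_text(write_yolo_labels(list(boxes)))
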