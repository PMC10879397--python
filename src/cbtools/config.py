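"""Configuration defaults, YAML loading and the pluggable detector contract."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Callable, Mapping, Sequence

import yaml

from .tiles import Box, Patch

__all__ = ["DEFAULT_CONFIG", "Detector", "load_config", "merge_config", "config_hash"]

#: A detector is any stateless callable (Patch) -> list[Box] with confidence,
#: deterministic for fixed inputs and seed.
Detector = Callable[[Patch], Sequence[Box]]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["simulate", "preprocess", "detect", "evaluate", "mine", "grade"],
    "detector": "baseline",  # "baseline" | "prediction-files"
    "predictions_dir": None,
    "input_images": None,
    "simulate": {
        "n_images": 8,
        "n_cb": 4,
        "n_other": 2,
        "stain_mode": "purple",
        "image_size": 256,
    },
    "tile": {"tile_size": 512},
    "preprocess": {"enabled": True, "fill_ratio": 0.5, "dilation_radius": 2},
    "criteria": {
        "min_equiv_diameter_um": 5.13,
        "aspect_ratio_range": [0.7, 1.3],
        "um_per_px": 0.12,
    },
    "evaluate": {"iou_threshold": 0.5, "ladder": True},
    "mining": {"iou_threshold": 0.5, "cap_ratio": 1.0, "size_band": [5.0, 95.0]},
    "grading": {"confidence_cut": 0.25, "expected_hpfs": 10},
    "split": {"test_frac": 0.05, "train_frac_of_rest": 0.8},
}


def merge_config(overrides: Mapping | None = None) -> dict:
    """Defaults overlaid with ``overrides`` (one level of nesting deep)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (overrides or {}).items():
        if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = copy.deepcopy(value) if isinstance(value, (dict, list)) else value
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file over the defaults."""
    overrides = None
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
    return merge_config(overrides)


def config_hash(config: Mapping) -> str:
    """Stable hash of a fully-resolved configuration."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()
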