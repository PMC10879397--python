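"""Stage orchestration: simulate/tile -> preprocess -> detect -> evaluate ->
mine -> grade, with a reproducibility manifest per run.

Each stage reads and writes plain files under the working directory
(``images/``, ``labels/``, ``preprocessed/``, ``predictions/``,
``labels2/``, ``reports/``), so any stage can also be run in isolation
through the CLI against externally produced inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

from . import __version__, io
from .candidates import CandidateCriteria, baseline_detect
from .config import config_hash, merge_config
from .evaluation import DEFAULT_IOU_LADDER, mean_ap
from .grading import grade_slide
from .mining import MiningConfig, build_two_class_dataset, mine_false_positives
from .preprocess import PreprocessConfig, remove_background
from .synthetic import SceneSpec, generate_patch
from .tiles import Patch, tile_image

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "tile", "preprocess", "detect", "evaluate", "mine", "grade")


class PipelineError(RuntimeError):
    """A stage could not run, naming the stage and the missing input."""


def _criteria(cfg: Mapping) -> CandidateCriteria:
    c = cfg["criteria"]
    return CandidateCriteria(
        min_equiv_diameter_um=c["min_equiv_diameter_um"],
        aspect_ratio_range=tuple(c["aspect_ratio_range"]),
        um_per_px=c["um_per_px"],
    )


def _require_dir(stage: str, path: Path) -> Path:
    if not path.is_dir():
        raise PipelineError(f"stage {stage!r}: missing input directory {path}")
    return path


def _write_json(path: Path, payload) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _stage_simulate(cfg: Mapping, workdir: Path) -> dict:
    sim = cfg["simulate"]
    images_dir = workdir / "images"
    labels_dir = workdir / "labels"
    images_dir.mkdir(parents=True, exist_ok=True)
    labels = {}
    for i in range(sim["n_images"]):
        spec = SceneSpec(
            n_cb=sim["n_cb"],
            n_other=sim["n_other"],
            stain_mode=sim["stain_mode"],
            image_size=sim["image_size"],
            um_per_px=cfg["criteria"]["um_per_px"],
            seed=cfg["seed"] * 100_003 + i,
        )
        patch, boxes = generate_patch(spec)
        stem = f"patch_{i:04d}"
        io.save_image(images_dir / f"{stem}.png", patch.pixels)
        labels[stem] = boxes
    io.write_labels_dir(labels, labels_dir)
    return {"n_images": sim["n_images"]}


def _stage_tile(cfg: Mapping, workdir: Path) -> dict:
    src = cfg.get("input_images")
    if not src:
        raise PipelineError("stage 'tile': config key 'input_images' not set")
    src_dir = _require_dir("tile", Path(src))
    out_dir = workdir / "images"
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for stem, path in io.list_images(src_dir).items():
        for t in tile_image(
            io.load_image(path),
            tile_size=cfg["tile"]["tile_size"],
            um_per_px=cfg["criteria"]["um_per_px"],
        ):
            x, y = t.origin_xy
            io.save_image(out_dir / f"{stem}_x{x}_y{y}.png", t.pixels)
            n += 1
    return {"n_tiles": n}


def _stage_preprocess(cfg: Mapping, workdir: Path) -> dict:
    pp = cfg["preprocess"]
    if not pp.get("enabled", True):
        return {"skipped": True}
    images_dir = _require_dir("preprocess", workdir / "images")
    out_dir = workdir / "preprocessed"
    out_dir.mkdir(parents=True, exist_ok=True)
    pconf = PreprocessConfig(
        dilation_radius=pp["dilation_radius"], fill_ratio=pp["fill_ratio"]
    )
    n = 0
    for stem, path in io.list_images(images_dir).items():
        patch = Patch(io.load_image(path), um_per_px=cfg["criteria"]["um_per_px"])
        io.save_image(out_dir / f"{stem}.png", remove_background(patch, pconf).pixels)
        n += 1
    return {"n_images": n}


def _detect_input_dir(cfg: Mapping, workdir: Path) -> Path:
    pre = workdir / "preprocessed"
    if cfg["preprocess"].get("enabled", True) and pre.is_dir():
        return pre
    return workdir / "images"


def _stage_detect(cfg: Mapping, workdir: Path) -> dict:
    out_dir = workdir / "predictions"
    if cfg["detector"] == "prediction-files":
        src = cfg.get("predictions_dir")
        if not src:
            raise PipelineError(
                "stage 'detect': detector is 'prediction-files' but "
                "'predictions_dir' is not set"
            )
        preds = io.read_labels_dir(_require_dir("detect", Path(src)), has_confidence=True)
        io.write_labels_dir(preds, out_dir)
        return {"source": str(src), "n_images": len(preds)}
    images_dir = _require_dir("detect", _detect_input_dir(cfg, workdir))
    criteria = _criteria(cfg)
    preds = {}
    for stem, path in io.list_images(images_dir).items():
        patch = Patch(io.load_image(path), um_per_px=criteria.um_per_px)
        preds[stem] = baseline_detect(patch, criteria)
    io.write_labels_dir(preds, out_dir)
    return {"source": "baseline", "n_images": len(preds)}


def _stage_evaluate(cfg: Mapping, workdir: Path) -> dict:
    gts = io.read_labels_dir(_require_dir("evaluate", workdir / "labels"))
    preds = io.read_labels_dir(
        _require_dir("evaluate", workdir / "predictions"), has_confidence=True
    )
    ladder = (
        DEFAULT_IOU_LADDER
        if cfg["evaluate"].get("ladder", True)
        else [cfg["evaluate"]["iou_threshold"]]
    )
    result = mean_ap(preds, gts, thresholds=ladder)
    payload = {
        "map50": result.map50,
        "map_overall": result.map_overall,
        "ap_per_threshold": {f"{t:.2f}": v for t, v in result.ap_per_threshold.items()},
        "per_class_ap50": {str(k): v for k, v in result.per_class_ap50.items()},
        "precision": result.precision,
        "recall": result.recall,
    }
    _write_json(workdir / "reports" / "metrics.json", payload)
    return payload


def _stage_mine(cfg: Mapping, workdir: Path) -> dict:
    m = cfg["mining"]
    gts = io.read_labels_dir(_require_dir("mine", workdir / "labels"))
    preds = io.read_labels_dir(
        _require_dir("mine", workdir / "predictions"), has_confidence=True
    )
    mconf = MiningConfig(
        iou_threshold=m["iou_threshold"],
        cap_ratio=m["cap_ratio"],
        size_band=tuple(m["size_band"]),
    )
    negatives = mine_false_positives(preds, gts, mconf)
    merged = build_two_class_dataset(gts, negatives, iou_threshold=m["iou_threshold"])
    io.write_labels_dir(merged, workdir / "labels2")
    n_neg = sum(len(v) for v in negatives.values())
    return {"n_negatives": n_neg}


def _stage_grade(cfg: Mapping, workdir: Path) -> dict:
    g = cfg["grading"]
    preds = io.read_labels_dir(
        _require_dir("grade", workdir / "predictions"), has_confidence=True
    )
    cut = g["confidence_cut"]
    counts = {
        stem: sum(
            b.class_id == 0 and (b.confidence or 0.0) >= cut for b in boxes
        )
        for stem, boxes in sorted(preds.items())
    }
    report = grade_slide(list(counts.values()), expected_n=g["expected_hpfs"])
    payload = {
        "per_field_counts": counts,
        "mean_count": report.mean_count,
        "grade": report.grade,
        "confidence_cut": cut,
    }
    _write_json(workdir / "reports" / "grades.json", payload)
    return payload


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "tile": _stage_tile,
    "preprocess": _stage_preprocess,
    "detect": _stage_detect,
    "evaluate": _stage_evaluate,
    "mine": _stage_mine,
    "grade": _stage_grade,
}


def run_pipeline(config: Mapping | None, workdir: str | Path) -> dict:
    """Execute the configured stages in canonical order; write a manifest.

    Returns the manifest: resolved config hash, seed, package versions and
    per-stage status/summary.  Reruns with identical config and seed
    produce byte-identical reports.
    """
    import numpy
    import skimage

    cfg = merge_config(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in cfg["stages"] if s not in _STAGE_FUNCS]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]

    manifest: dict = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "versions": {
            "cbtools": __version__,
            "numpy": numpy.__version__,
            "scikit-image": skimage.__version__,
        },
        "stages": {},
    }
    for stage in stages:
        logger.info("running stage %s", stage)
        summary = _STAGE_FUNCS[stage](cfg, workdir)
        manifest["stages"][stage] = {"status": "success", **summary}
    _write_json(workdir / "manifest.json", manifest)
    return manifest
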