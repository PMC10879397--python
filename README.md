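# cbtools

A detector-agnostic toolkit for centroblast (CB) detection and follicular-
lymphoma grading on H&E-stained tissue patches. It covers everything around
the deep-learning detector itself, which is deliberately pluggable: the
pipeline consumes YOLO-format prediction files from any trained model, or
falls back to a built-in classical baseline so it runs end to end with no
weights.

## What's inside

| module | purpose |
|---|---|
| `cbtools.tiles` | patch tiling, YOLO-dialect label I/O, dataset splitting (5% test, 80/20 train/val, ceiling convention), accounting tables |
| `cbtools.preprocess` | luminance histogram equalization, Otsu binarization, and the background-removal pipeline (mask, dilate, small-contour fill, white-out) |
| `cbtools.candidates` | classical cell segmentation stand-in, equivalent-diameter (≥ 5.13 μm) and aspect-ratio (0.7–1.3) candidate filter, baseline detector |
| `cbtools.evaluation` | IoU, greedy confidence-ordered matching, PR curves, AP (all-point interpolation), mAP@0.5 and mAP@[0.5:0.95:0.05] |
| `cbtools.mining` | hard-negative mining: false positives become a capped, size-banded non-CB class merged into a two-class dataset |
| `cbtools.grading` | WHO grade (I: ≤5, II: 6–15, III: >15 CBs/HPF) from per-field counts; cohort tabulation |
| `cbtools.synthetic` | deterministic H&E-like scene generator (purple/pink stain modes) with exact bounding-box ground truth, plus a detection perturbation simulator |
| `cbtools.pipeline` / `cbtools.cli` | stage orchestration with a reproducibility manifest; `cbtools` command-line entry point |

**Caveat on grading:** a 512×512 patch at 0.12 μm/px covers ~61 μm square,
much smaller than a conventional microscope high-power field. By default one
patch counts as one field; set the aggregation to your optics before reading
grades clinically.

## CLI

```bash
cbtools simulate --n-images 8 --out data/            # synthetic dataset
cbtools tile --in slides/ --out data/images --tile-size 512
cbtools preprocess --in data/images --out data/preprocessed
cbtools candidates --in data/images --out preds/     # baseline detector
cbtools evaluate --gt data/labels --pred preds/      # mAP report (JSON)
cbtools mine-negatives --gt data/labels --pred preds/ --out labels2/
cbtools split --images data/images --test-frac 0.05 --train-frac 0.8
cbtools grade --pred preds/ --conf 0.25
cbtools run --config config.yaml --workdir out/      # full pipeline + manifest
```

The directory layout is the de-facto YOLO convention: `images/x.png` pairs
with `labels/x.txt` (`class cx cy w h`, normalized; predictions append a
confidence column).

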