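# wsldetect

Tiled two-stage detection of **white spot lesions** (WSLs) on high-resolution
intra-oral photographs — with the full evaluation suite (pixel-wise Cohen's
kappa, COCO-style mAP, F1–IoU curves), dataset-geometry analyses, score-CAM
explainability, and a seeded synthetic-photograph generator so the whole
toolchain runs end-to-end with no trained weights and no data download.

## The problem

WSLs are pre-cavitation enamel demineralization — opaque white patches,
common during fixed-appliance orthodontic treatment. On a frontal intra-oral
photograph of ~4000 × 3000 px, a typical WSL bounding box covers only ~2900 px
of area. The conventional detection recipe resizes the whole photograph to a
640 px square first, which multiplies box areas by ~0.16² ≈ 0.026: the median
lesion drops to ~75 px, deep below the COCO small-object boundary
(32² = 1024 px), and the enamel texture that makes lesions visible is gone.

`wsldetect` implements the tiled two-stage alternative:

```
photograph ──resize──▶ tooth detector ──NMS──▶ tooth boxes
                                                  │ union crop (full resolution)
                                                  ▼
                          640 px tiles, 50 px overlap  +  one holistic pass
                                                  │ lesion detector per tile
                                                  ▼
                      remap to original frame ──▶ final NMS ──▶ detections
```

Teeth are large enough to survive the downscale, so the cheap first stage
finds *where* to look; lesions are then detected at native resolution inside
overlapping tiles, and a final NMS merges duplicates from adjacent tiles and
the holistic pass. The pipeline is **detector-agnostic**: any backend with a
`detect(image)` method plugs into either stage, and the bundled classical
brightness-blob detector makes everything runnable out of the box.

Metrics follow the object-detection canon: greedy one-to-one IoU matching,
101-point-interpolated AP@0.5 and mAP@0.5:0.95, F1 over IoU thresholds at a
fixed operating cutoff, and — as the agreement-centric headline metric —
pixel-wise Cohen's kappa between the rasterized prediction and annotation
masks, with percentile-bootstrap CIs over images. See `docs/methods.md` for
definitions, conventions and limitations.

## Worked example

Run both arms with the *identical* bundled lesion detector on the default
synthetic study conditions (4000 × 3000 px, two arches, log-normal lesion
areas with median 2898 px, peri-gingival placement bias):

```python
from wsldetect import GeneratorConfig, tw_detect, baseline_detect, evaluate_detections
from wsldetect.detectors import BlobDetector, lesion_blob_config, tooth_blob_config
from wsldetect.synthetic import iter_images

cfg = GeneratorConfig()                      # 4000 x 3000 px study conditions
tooth = BlobDetector(tooth_blob_config())
lesion = BlobDetector(lesion_blob_config())  # identical detector in both arms

tw, base, gts, dims = {}, {}, {}, {}
for image, rec in iter_images(cfg, 8, seed=7):
    gts[rec.image_id] = rec.boxes("wsl")
    dims[rec.image_id] = (rec.width, rec.height)
    tw[rec.image_id] = tw_detect(image, tooth, lesion)
    base[rec.image_id] = baseline_detect(image, lesion)

for name, dets in (("tiled", tw), ("baseline", base)):
    r = evaluate_detections(dets, gts, dims)
    print(f"{name:8s} kappa={r.kappa:.3f} AP@0.5={r.ap50:.3f} "
          f"mAP@0.5:0.95={r.map_50_95:.3f} TP/FN/FP={r.tp}/{r.fn}/{r.fp}")
```

prints

```
tiled    kappa=0.989 AP@0.5=0.976 mAP@0.5:0.95=0.923 TP/FN/FP=91/0/4
baseline kappa=0.773 AP@0.5=0.406 mAP@0.5:0.95=0.345 TP/FN/FP=37/54/0
```

Reading: with the same detector, tiling at native resolution recovers
essentially every planted lesion (kappa 0.99, AP@0.5 0.98), while the
resize-first baseline misses over half of them (54 FN of 91 lesions) because
median-sized lesions shrink below what the detector can resolve — the
small-object failure mode the tiled pipeline exists to avoid. TP/FN/FP are
counted at the F1-maximizing confidence cutoff at IoU 0.5.

## Command line

Every stage is also a subcommand (`wsldetect --help`):

```bash
wsldetect simulate --n 20 --out data/ --seed 1           # images + YOLO labels + manifest
wsldetect detect   --mode tw --images data/images --out preds/
wsldetect detect   --mode baseline --images data/images --out preds_base/
wsldetect evaluate --pred preds/ --gt data/labels --dims data/manifest.csv \
                   --out report.json --curves curves/
wsldetect analyze  --labels data/labels --dims data/manifest.csv --out analysis/
wsldetect explain  --image data/images/img_0000.png --target iou \
                   --gt data/labels/img_0000.txt --out cam.png
wsldetect split    --dims data/manifest.csv --out split.json
```

Labels use the LabelImg-compatible YOLO-txt dialect (normalized
`class cx cy w h`, predictions append a confidence column); COCO-JSON export
is available for interop. Every run writes a `runlog.json` with the seed,
a config hash and library versions.

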