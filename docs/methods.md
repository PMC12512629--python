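# Methods

## The problem and the procedure

White spot lesions (WSLs) — opaque, pre-cavitation enamel demineralization,
common during fixed-appliance orthodontic treatment — are small objects in
frontal intra-oral photographs. A typical photograph is ~4000 × 3000 px while
the median WSL bounding box covers only ~2900 px of area; squeezing the whole
photograph into the 640 px input square of a standard one-stage detector
multiplies box areas by ~0.16² ≈ 0.026, pushing the median WSL far below the
COCO small-object boundary (1024 px = 32²) and discarding the enamel texture
the diagnosis rests on.

The package implements the tiled two-stage alternative as a
detector-agnostic pipeline (`wsldetect.pipeline.tw_detect`):

1. **Tooth stage.** Proportionally resize the photograph to fit 640 × 640
   (isotropic scale, no letterboxing), run the tooth detector, apply greedy
   NMS, and lift the surviving boxes back to the original frame. Teeth are
   large even after resizing, so this stage tolerates the downscale.
2. **Crop.** Cut the minimal rectangle containing all tooth boxes (optional
   margin, default 0) out of the *full-resolution* image.
3. **Tiling.** Cover the crop with 640 px sliding windows overlapping by
   50 px; run the lesion detector on every tile at native resolution, plus
   one holistic pass on the whole crop resized to 640.
4. **Merge.** Map tile boxes back by pure translation and holistic boxes by
   inverse rescale; pool everything and apply a final NMS.

The comparison arm (`baseline_detect`) is the conventional treatment:
resize the whole image once, detect, lift the boxes back.

Everything is detector-agnostic: any object with `detect(image)` returning
box/label/confidence triples plugs in, so a trained network can replace the
bundled classical detector without touching the pipeline.

## Coordinate conventions and numerical choices

* Boxes are 0-based, half-open `[x_min, x_max) × [y_min, y_max)` everywhere;
  YOLO-normalized centre/size coordinates are converted only at the I/O
  boundary (`wsldetect.formats`).
* Box coordinates stay fractional across frame changes; integer pixels are
  taken only where a raster is indexed (crop windows, rasterized masks).
  This makes translation round trips exact and resize round trips exact to
  float precision; the crop window is the integer floor/ceil hull of the
  fractional union box. A box rescaled *forward* is clipped against the
  exact scaled extent `(w·s, h·s)` rather than the rounded integer canvas,
  which would otherwise inject up to `0.5/s` px of border error.
* NMS is greedy by descending confidence, ties broken by input order, and
  suppresses on IoU **strictly greater** than the threshold; both NMS
  thresholds default to 0.5 and are configurable (no published value
  exists for either stage).
* Tile offsets per axis are `0, s, 2s, …` (stride `s = window − overlap`)
  while the window fits, plus one final tile clamped to `dim − window` so
  coverage is complete without padding; an axis shorter than the window
  yields a single clamped tile. Any object with both sides ≤ `overlap` is
  guaranteed to lie wholly inside at least one tile; the stride itself
  gives no such guarantee (a 100 px box straddling a seam of a 590 px
  stride grid can avoid every window), which is why the overlap — not the
  stride — is the "no lesion split" parameter.
* The holistic pass resizes the crop to the fit size before detection —
  a fixed input scale is the only consistent way to feed "the whole crop"
  to the same detector — and its boxes re-enter the pool through the
  inverse rescale. Tile and holistic detections are merged by one pooled
  final NMS with no border-specific heuristics.
* If the tooth stage finds nothing, the full image becomes the crop
  (logged), so the lesion stage still runs.

## Metrics

* **Matching** is greedy and confidence-ordered: each detection takes the
  unmatched ground truth of highest IoU provided IoU ≥ threshold, one-to-one,
  so TP + FN = #GT by construction.
* **AP** uses the COCO 101-point interpolation (mean over the recall grid
  {0, 0.01, …, 1} of the maximum precision at recall ≥ grid point);
  `mAP@0.5:0.95` averages AP over IoU thresholds 0.50–0.95 in steps of
  0.05. The test suite cross-checks AP against an independent brute-force
  scan of the same grid. ROC/AUC are deliberately absent: detection has no
  true-negative event.
* **TP/FN/FP and F1** are reported at the confidence cutoff that maximizes
  dataset-level F1 at IoU 0.5; the cutoff is part of the report (no
  published operating point exists). The F1-over-IoU curve holds that
  cutoff fixed so it shows pure localization degradation, and is provably
  non-increasing in the threshold.
* **Pixel-wise Cohen's kappa** rasterizes each box set per image as the
  union of filled rectangles at original resolution, accumulates one 2 × 2
  pixel confusion matrix over the whole dataset, and applies the standard
  chance correction. Pooling (rather than averaging per-image kappas) is
  the default because it yields a single dataset-level value and remains
  defined when individual images have no lesions; per-image averaging is
  available behind a flag. Both-raters-constant is signalled as undefined.
* **Confidence intervals** are nonparametric percentile bootstraps over
  images (default 1000 replicates, seeded). No multiplicity correction is
  applied anywhere.
* **χ²** for 2 × 2 tables is the Pearson statistic without continuity
  correction, 1 df; zero expected counts are an error.
* Quantiles (median/IQR of box areas) use linear interpolation (type 7),
  stated because published IQRs cannot disambiguate the convention.

## Dataset-geometry analyses

Absolute heatmaps accumulate boxes in each image's normalized unit square
with exact fractional cell coverage (so total mass equals Σ normalized
areas × cell count). Tooth-relative heatmaps first assign each lesion to
the tooth of **maximal intersection area** — max IoU would be near zero for
every small lesion inside a large tooth — then rasterize the lesion in the
host tooth's unit square; unassignable lesions are dropped and counted.
Crown coverage is the exact area of the union of (tooth-clipped) lesion
rectangles over the tooth-box area, computed with a polygon union; it uses
bounding-box geometry because boxes are the only geometry annotations
provide — a stated limitation, not an approximation choice.

## Score-CAM

Explainability is gradient-free: per activation channel, min-max normalize,
upsample bilinearly to image size, soft-mask the image by elementwise
product, and evaluate a target score; channel weights are the softmax of
score increases over the unmasked baseline, and the CAM is the rectified
weighted sum of the normalized upsampled maps. Constant channels normalize
to zero (they carry no spatial information; this also pins all-zero
channels to zero output). Two target scores ship: maximum detection
confidence, and maximum IoU between detections on the masked image and a
reference annotation — the latter asks where the model must look to draw
boxes that agree with the annotator. Which layer's channels to expose is a
backend concern; the bundled test backend uses hand-specified indicator
bands, for which the CAM has a closed form the tests check to 1e-9.

## Synthetic data: what it emulates, what it does not

The generator plants the study conditions so every stage is testable
without any photograph archive:

| parameter | default | rationale |
|---|---|---|
| canvas | 4000 × 3000 px | typical reflex-camera intra-oral resolution |
| teeth | 2 arches × 8 | frontal view, mild arch curvature, ±10% size jitter |
| lesion box area | log-normal, median 2898 px, σ(log) = 0.731 | right-skewed; median matches the reported value, σ fitted so the implied IQR (≈1771–4744) approximates the reported 1895–5080 |
| lesions per image | Poisson(12) | ≈842 lesions / 66 images in the reference test split |
| peripheral placement | p = 0.8, 60% of those on the gum-side edge | peri-gingival concentration of WSLs |
| upper-jaw share | 0.65 | lesions reported more frequent in the upper jaw |
| brightness | background 45 / mucosa 95 / tooth 175 / lesion 228, Gaussian noise σ = 6 | contrast ladder, see below |

Length-like parameters scale with the canvas (areas with the canvas area),
so the 1600 × 1200 test preset is a geometrically faithful miniature.
Non-peripheral lesions are placed wholly inside the central half of the
tooth, so the outer-band mass fraction of the tooth-relative heatmap tracks
the configured peripheral probability; lesion placements keep a blur-scaled
separation so two planted blobs never merge into one connected component.
All randomness flows through one seeded generator — label files are
byte-identical across runs with the same seed.

The brightness ladder is chosen so the bundled blob detector (threshold →
morphological opening → connected components → area filter) is near-perfect
on full-resolution tiles but degrades sharply once the image is resized to
640 px, where a median lesion is an ~8 px blob that the opening erodes and
the area filter drops. That is a *fixture property*: it recreates the
small-object failure mode by construction so the tiled-vs-resize comparison
is meaningful, and it is the package's stand-in for the real phenomenon
(texture loss under downscaling), not a model of enamel optics. Passing
tests therefore demonstrate the pipeline's geometric and statistical
machinery, and the direction of the tiling benefit — not clinical accuracy
on photographs, which requires trained detectors and real data. The
generator also omits brackets and appliances, specular highlights, camera
optics, and inter-annotator variability.

## Problem sizes

The heavy end-to-end comparison runs 50 synthetic photographs at full
4000 × 3000 resolution with identical lesion detectors in both arms
(~4 minutes single-core); statistical-fidelity checks use 40 preset images
(≈600 lesions); randomized geometry and metric-oracle checks use 1000 and
100 instances respectively. `scripts/acceptance.py` re-runs the 50-image
comparison from scratch at whatever seed it is given.

## Known limitations

* The reference detector's confidence (mean component saliency) is a
  plumbing heuristic, not a calibrated probability; PR curves over it are
  structurally valid but their absolute shape is fixture-dependent.
* Crown coverage over bounding boxes overstates lesion area relative to
  hand-traced outlines.
* The published 2 × 2 χ² for the small-size shift is not reconstructed —
  the underlying denominators are not recoverable from the printed counts —
  so the operation ships as a generic test applied to the synthetic shift
  table.
* Holistic-pass detections that survive the final NMS without a matching
  tile detection inherit baseline-quality boxes; no border or provenance
  heuristic filters them, by design.
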