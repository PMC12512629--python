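"""Orchestration of the tiled two-stage detection procedure.

The two-stage procedure (``tw_detect``):

1. proportionally resize the photograph to fit a 640 px square;
2. detect teeth on the resized image, NMS, lift the boxes back to the
   original frame;
3. crop the union of all tooth boxes out of the *full-resolution* image;
4. cover the crop with overlapping 640 px windows (50 px overlap) and run
   the lesion detector on every tile at native resolution, plus one
   holistic pass on the whole crop resized to the fit size;
5. map every lesion box back to the original frame (tiles: translation;
   holistic: inverse rescale then translation) and apply a final NMS.

The comparison arm (``baseline_detect``) is the conventional treatment:
resize the whole photograph to the fit size, detect once, lift the boxes
back — the regime in which a median-sized lesion shrinks from ~2900 px to
~75 px of area and becomes a small object in the COCO sense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detectors import Detector
from .geometry import BoundingBox, Detection, nms
from .slicing import (
    proportional_resize,
    rescale_box,
    resize_image,
    tile_grid,
    to_original,
    union_crop,
)
from .geometry import ImageRecord

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "tw_detect", "baseline_detect"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the two-stage pipeline."""

    fit: int = 640               # resize target square, px
    window: int = 640            # tile size, px
    overlap: int = 50            # tile overlap, px
    crop_margin: float = 0.0     # union-crop expansion, px
    tooth_nms_iou: float = 0.5   # NMS threshold after the tooth stage
    final_nms_iou: float = 0.5   # NMS threshold over pooled lesion boxes
    confidence_floor: float = 0.0  # drop reported detections below this

    def __post_init__(self) -> None:
        if not (self.window > self.overlap >= 0):
            raise ValueError("need window > overlap >= 0")
        for name in ("tooth_nms_iou", "final_nms_iou"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")


def _record_for(image: np.ndarray) -> ImageRecord:
    h, w = image.shape[:2]
    return ImageRecord(image_id="<in-memory>", width=w, height=h)


def detect_teeth(image: np.ndarray, tooth_detector: Detector,
                 cfg: PipelineConfig) -> list[Detection]:
    """Tooth stage: resize to fit, detect, NMS, lift to the original frame."""
    h, w = image.shape[:2]
    tr = proportional_resize(w, h, cfg.fit)
    resized = resize_image(image, tr)
    dets = nms(tooth_detector.detect(resized), cfg.tooth_nms_iou)
    out = []
    for d in dets:
        box = rescale_box(d.box, tr, direction="inverse")
        out.append(Detection(box, d.label, d.confidence))
    return out


def tw_detect(image: np.ndarray, tooth_detector: Detector,
              lesion_detector: Detector, cfg: PipelineConfig | None = None,
              ) -> list[Detection]:
    """Run the full tiled two-stage procedure on one photograph.

    Returns lesion detections in the original image frame, sorted by
    descending confidence.  If the tooth stage finds nothing the whole
    image is used as the crop (logged), so the lesion stage still runs.
    """
    cfg = cfg or PipelineConfig()
    h, w = image.shape[:2]
    record = _record_for(image)

    tooth_dets = detect_teeth(image, tooth_detector, cfg)
    if tooth_dets:
        crop_box = union_crop([d.box for d in tooth_dets], record,
                              margin=cfg.crop_margin)
    else:
        logger.warning("tooth stage found no teeth; falling back to full-image crop")
        crop_box = BoundingBox(0, 0, w, h)

    # crop at native resolution: integer pixel window containing the box
    cx0 = int(np.floor(crop_box.x_min))
    cy0 = int(np.floor(crop_box.y_min))
    cx1 = int(np.ceil(crop_box.x_max))
    cy1 = int(np.ceil(crop_box.y_max))
    crop = image[cy0:cy1, cx0:cx1]
    ch, cw = crop.shape[:2]

    pooled: list[Detection] = []

    grid = tile_grid(cw, ch, window=cfg.window, overlap=cfg.overlap)
    tw_px, th_px = grid.tile_size
    for tx, ty in grid.offsets:  # row-major, deterministic
        tile = crop[ty:ty + th_px, tx:tx + tw_px]
        for d in lesion_detector.detect(tile):
            pooled.append(Detection(
                to_original(d.box, tile_origin=(tx, ty), crop_origin=(cx0, cy0)),
                d.label, d.confidence))

    # holistic pass: the entire crop resized to the fit size
    holo_tr = proportional_resize(cw, ch, cfg.fit)
    holo = resize_image(crop, holo_tr)
    for d in lesion_detector.detect(holo):
        box = rescale_box(d.box, holo_tr, direction="inverse")
        pooled.append(Detection(
            to_original(box, crop_origin=(cx0, cy0)), d.label, d.confidence))

    pooled = [d for d in pooled if d.confidence >= cfg.confidence_floor]
    final = nms(pooled, cfg.final_nms_iou)
    final = [Detection(d.box.clip(w, h), d.label, d.confidence) for d in final]
    final.sort(key=lambda d: -d.confidence)
    return final


def baseline_detect(image: np.ndarray, lesion_detector: Detector,
                    cfg: PipelineConfig | None = None) -> list[Detection]:
    """Conventional single-pass arm: whole-image resize, detect, NMS,
    inverse-rescale to the original frame."""
    cfg = cfg or PipelineConfig()
    h, w = image.shape[:2]
    tr = proportional_resize(w, h, cfg.fit)
    resized = resize_image(image, tr)
    dets = [d for d in lesion_detector.detect(resized)
            if d.confidence >= cfg.confidence_floor]
    dets = nms(dets, cfg.final_nms_iou)
    out = []
    for d in dets:
        box = rescale_box(d.box, tr, direction="inverse").clip(w, h)
        out.append(Detection(box, d.label, d.confidence))
    out.sort(key=lambda d: -d.confidence)
    return out
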