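"""Seeded generator of intra-oral-photograph-like images with ground truth.

The generator emulates the geometry of frontal intra-oral photographs of
orthodontic patients: a dark oral background, a brighter mucosa/lip oval,
two arches of bright tooth-like rounded rectangles, and white-spot-lesion
blobs rendered as bright ellipses *inside* tooth boxes.  The planted
statistics mirror what such datasets look like:

* full-resolution canvas ~4000 x 3000 px (test preset 1600 x 1200);
* lesion box areas log-normal with median ~2898 px at full resolution
  (IQR roughly 1.9k-5.1k), scaled with image area at other presets;
* lesions concentrated in the peri-gingival periphery of their tooth
  (peripheral placement probability 0.8, biased toward the gum-side
  edge) and more frequent in the upper jaw.

Brightness contrasts are chosen so the bundled blob detector is
near-perfect on full-resolution tiles but degrades once the image is
squeezed into a 640 px square — the small-object regime a tiled pipeline
exists to avoid.  That is a fixture property of the generator, not a
claim about real enamel.

All randomness flows through one ``numpy.random.Generator``; a fixed seed
reproduces label files byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import BoundingBox, ImageRecord

__all__ = [
    "GeneratorConfig",
    "generate_image",
    "iter_images",
    "generate_dataset",
    "dataset_self_check",
    "SelfCheckReport",
]

_FULL_AREA = 4000 * 3000  # reference canvas the absolute defaults refer to


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic photograph generator.

    Length-like defaults (tooth size, blur, lesion areas) refer to the
    4000 x 3000 reference canvas and are scaled by ``linear_scale`` —
    sqrt of the area ratio — for other canvas sizes, so a 1600 x 1200
    preset is a geometrically faithful miniature.
    """

    width: int = 4000
    height: int = 3000
    teeth_per_arch: int = 8

    # brightness levels on the 0-255 scale (before the warm tint)
    background_level: float = 45.0
    mouth_level: float = 95.0
    tooth_level: float = 175.0
    lesion_level: float = 228.0
    noise_sd: float = 6.0

    # lesion placement statistics
    lesions_per_image_mean: float = 12.0
    lesion_area_median: float = 2898.0       # box area, px, at full resolution
    lesion_area_log_sigma: float = 0.731     # fits IQR ~1895-5080
    peripheral_prob: float = 0.8             # outer-25%-band placement
    gingival_prob: float = 0.6               # among peripheral: gum-side edge
    upper_jaw_prob: float = 0.65

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.teeth_per_arch < 1:
            raise ValueError("need at least one tooth per arch")
        if self.lesions_per_image_mean < 0:
            raise ValueError("lesion rate must be >= 0")
        if self.lesion_area_median <= 0 or self.lesion_area_log_sigma < 0:
            raise ValueError("lesion area distribution parameters invalid")
        for name in ("peripheral_prob", "gingival_prob", "upper_jaw_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def linear_scale(self) -> float:
        """Linear size of this canvas relative to the 4000x3000 reference."""
        return math.sqrt(self.width * self.height / _FULL_AREA)

    @property
    def scaled_area_median(self) -> float:
        """Lesion-box area median on this canvas (scales with image area)."""
        return self.lesion_area_median * self.linear_scale**2

    def preset(self, width: int, height: int) -> "GeneratorConfig":
        return replace(self, width=width, height=height)


def _tooth_layout(cfg: GeneratorConfig, rng: np.random.Generator,
                  ) -> list[tuple[BoundingBox, bool]]:
    """Two arch rows of jittered tooth boxes; returns (box, is_upper)."""
    w, h = cfg.width, cfg.height
    n = cfg.teeth_per_arch
    span = 0.72 * w                       # dental region spans ~72% of the width
    x_left = (w - span) / 2
    pitch = span / n
    tooth_w0 = 0.82 * pitch
    tooth_h0 = 0.165 * h
    gap = 0.045 * h                       # inter-arch gap
    teeth: list[tuple[BoundingBox, bool]] = []
    for upper in (True, False):
        for i in range(n):
            cx = x_left + (i + 0.5) * pitch
            u = (cx - w / 2) / (span / 2)      # -1 .. 1 across the arch
            curve = 0.035 * h * u * u          # mild arch curvature
            tw = tooth_w0 * rng.uniform(0.9, 1.1)
            th = tooth_h0 * rng.uniform(0.9, 1.1)
            if upper:
                y1 = h / 2 - gap / 2 - curve
                y0 = y1 - th
            else:
                y0 = h / 2 + gap / 2 + curve
                y1 = y0 + th
            x0 = cx - tw / 2
            box = BoundingBox(
                max(0.0, round(x0)), max(0.0, round(y0)),
                min(float(w), round(x0 + tw)), min(float(h), round(y1)))
            teeth.append((box, upper))
    return teeth


def _place_lesion(cfg: GeneratorConfig, rng: np.random.Generator,
                  tooth: BoundingBox, upper: bool) -> BoundingBox | None:
    """Sample one lesion box fully inside the tooth box (None if the
    tooth is too small to host a minimal lesion)."""
    area = rng.lognormal(mean=math.log(cfg.scaled_area_median),
                         sigma=cfg.lesion_area_log_sigma)
    aspect = rng.uniform(0.6, 1.6)
    bw = math.sqrt(area * aspect)
    bh = math.sqrt(area / aspect)
    # keep the box at most half the tooth along each axis so a peripheral
    # centre (outer 25% band) is always geometrically feasible
    bw = min(bw, 0.5 * tooth.width)
    bh = min(bh, 0.5 * tooth.height)
    if bw < 2 or bh < 2:
        return None
    peripheral = rng.random() < cfg.peripheral_prob

    def centre_range(lo: float, hi: float, side: float) -> tuple[float, float]:
        return lo + side / 2, hi - side / 2

    cx_lo, cx_hi = centre_range(tooth.x_min, tooth.x_max, bw)
    cy_lo, cy_hi = centre_range(tooth.y_min, tooth.y_max, bh)
    if peripheral:
        # centre in the outer 25% band of the tooth's unit square (1 px
        # shrunk so integer rounding cannot push it across the boundary)
        gum_edge = rng.random() < cfg.gingival_prob
        if gum_edge:
            edge = "top" if upper else "bottom"
        else:
            edge = rng.choice(["left", "right", "bottom" if upper else "top"])
        band_w = 0.25 * tooth.width - 1.0
        band_h = 0.25 * tooth.height - 1.0
        if edge == "top":
            cy_hi = min(cy_hi, tooth.y_min + band_h)
        elif edge == "bottom":
            cy_lo = max(cy_lo, tooth.y_max - band_h)
        elif edge == "left":
            cx_hi = min(cx_hi, tooth.x_min + band_w)
        else:
            cx_lo = max(cx_lo, tooth.x_max - band_w)
    else:
        # mid-crown lesion: the whole box stays inside the central half of
        # the tooth, so central placements put no mass in the outer band
        # and the band-mass fraction tracks peripheral_prob by design
        cx_lo = max(cx_lo, tooth.x_min + 0.25 * tooth.width + bw / 2 + 1.0)
        cx_hi = min(cx_hi, tooth.x_max - 0.25 * tooth.width - bw / 2 - 1.0)
        cy_lo = max(cy_lo, tooth.y_min + 0.25 * tooth.height + bh / 2 + 1.0)
        cy_hi = min(cy_hi, tooth.y_max - 0.25 * tooth.height - bh / 2 - 1.0)
    if cx_lo > cx_hi or cy_lo > cy_hi:
        return None
    cx = rng.uniform(cx_lo, cx_hi)
    cy = rng.uniform(cy_lo, cy_hi)
    x0 = round(cx - bw / 2)
    y0 = round(cy - bh / 2)
    x1 = max(x0 + 2, round(cx + bw / 2))
    y1 = max(y0 + 2, round(cy + bh / 2))
    box = BoundingBox(x0, y0, x1, y1)
    if not tooth.contains(box):
        box = BoundingBox(max(x0, tooth.x_min), max(y0, tooth.y_min),
                          min(x1, tooth.x_max), min(y1, tooth.y_max))
    return box


def generate_image(cfg: GeneratorConfig, rng: np.random.Generator,
                   image_id: str = "synthetic") -> tuple[np.ndarray, ImageRecord]:
    """Render one synthetic photograph and its ground-truth record.

    Returns ``(uint8 RGB array of shape (height, width, 3), ImageRecord)``
    with annotations labelled ``tooth`` and ``wsl``.
    """
    w, h = cfg.width, cfg.height
    s = cfg.linear_scale
    lum = np.full((h, w), cfg.background_level, dtype=np.float32)

    # mucosa / lip oval behind the arches
    yy, xx = np.ogrid[:h, :w]
    oval = (((xx - w / 2) / (0.46 * w)) ** 2
            + ((yy - h / 2) / (0.40 * h)) ** 2) <= 1.0
    lum[oval] = cfg.mouth_level

    teeth = _tooth_layout(cfg, rng)
    annotations: list[tuple[BoundingBox, str]] = []
    for box, _ in teeth:
        lvl = cfg.tooth_level + rng.uniform(-6, 6)
        lum[int(box.y_min):int(box.y_max), int(box.x_min):int(box.x_max)] = lvl
        annotations.append((box, "tooth"))

    upper_teeth = [b for b, up in teeth if up]
    lower_teeth = [b for b, up in teeth if not up]
    n_lesions = int(rng.poisson(cfg.lesions_per_image_mean))
    lesion_boxes: list[BoundingBox] = []
    # separate lesions by a blur-scaled margin so two planted blobs never
    # merge into one connected component
    sep = 2.0 + 4.0 * s
    for _ in range(n_lesions):
        upper = rng.random() < cfg.upper_jaw_prob
        pool = upper_teeth if upper else lower_teeth
        tooth = pool[int(rng.integers(len(pool)))]
        box = None
        for _attempt in range(5):
            cand = _place_lesion(cfg, rng, tooth, upper)
            if cand is None:
                continue
            grown = BoundingBox(cand.x_min - sep, cand.y_min - sep,
                                cand.x_max + sep, cand.y_max + sep)
            if all(grown.intersection(b) == 0.0 for b in lesion_boxes):
                box = cand
                break
        if box is None:
            continue
        cy = (box.y_min + box.y_max) / 2
        cx = (box.x_min + box.x_max) / 2
        ry = max(box.height / 2, 1.0)
        rx = max(box.width / 2, 1.0)
        y0, y1 = int(box.y_min), int(box.y_max)
        x0, x1 = int(box.x_min), int(box.x_max)
        ly, lx = np.ogrid[y0:y1, x0:x1]
        inside = (((lx + 0.5 - cx) / rx) ** 2 + ((ly + 0.5 - cy) / ry) ** 2) <= 1.0
        patch = lum[y0:y1, x0:x1]
        patch[inside] = cfg.lesion_level + rng.uniform(-4, 4)
        lesion_boxes.append(box)
        annotations.append((box, "wsl"))

    # soften edges a touch (camera-ish blur, scaled with the canvas)
    sigma = max(0.8, 2.0 * s)
    lum = gaussian_filter(lum, sigma=sigma)
    if cfg.noise_sd > 0:
        lum = lum + rng.normal(0.0, cfg.noise_sd, size=lum.shape).astype(np.float32)
    lum = np.clip(lum, 0, 255)

    # warm tint: enamel slightly yellowish, applied globally
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[..., 0] = np.clip(lum * 1.02, 0, 255).astype(np.uint8)
    image[..., 1] = np.clip(lum * 0.97, 0, 255).astype(np.uint8)
    image[..., 2] = np.clip(lum * 0.88, 0, 255).astype(np.uint8)

    record = ImageRecord(image_id=image_id, width=w, height=h,
                         annotations=annotations)
    return image, record


def iter_images(cfg: GeneratorConfig, n_images: int, seed: int,
                ) -> Iterator[tuple[np.ndarray, ImageRecord]]:
    """Stream ``(image, record)`` pairs without keeping them all in memory.

    Deterministic for a given ``(cfg, n_images, seed)``; image ids are
    ``img_0000``, ``img_0001``, ...
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    for i in range(n_images):
        yield generate_image(cfg, rng, image_id=f"img_{i:04d}")


def generate_dataset(cfg: GeneratorConfig, n_images: int, seed: int,
                     out_dir: str | Path | None = None,
                     ) -> list[ImageRecord]:
    """Generate a dataset; optionally persist it to disk.

    With ``out_dir`` set, writes ``images/<id>.png``,
    ``labels/<id>.txt`` (YOLO dialect: class 0 = tooth, 1 = wsl) and
    ``manifest.csv`` (image_id, width, height).  Returns the records
    either way.  The config is validated (its constructor raises) before
    any file is written.
    """
    from . import formats  # local import: formats depends on geometry only

    records: list[ImageRecord] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "labels").mkdir(parents=True, exist_ok=True)
    for image, record in iter_images(cfg, n_images, seed):
        records.append(record)
        if out is not None:
            from PIL import Image

            Image.fromarray(image).save(out / "images" / f"{record.image_id}.png")
            formats.write_yolo_labels(
                out / "labels" / f"{record.image_id}.txt",
                record.annotations, record.width, record.height)
    if out is not None:
        formats.write_manifest(out / "manifest.csv", records)
    return records


@dataclass
class SelfCheckReport:
    passed: bool
    messages: list[str] = field(default_factory=list)


def dataset_self_check(records: list[ImageRecord],
                       cfg: GeneratorConfig) -> SelfCheckReport:
    """Verify generator invariants on a set of records.

    Checks: every box inside its image; every lesion box inside some
    tooth box of the same image; and, when >= 200 lesions are present,
    that the empirical lesion-area median is within 20% of the configured
    (canvas-scaled) median.
    """
    messages: list[str] = []
    areas: list[float] = []
    for rec in records:
        teeth = rec.boxes("tooth")
        for box, label in rec.annotations:
            if not (0 <= box.x_min and box.x_max <= rec.width
                    and 0 <= box.y_min and box.y_max <= rec.height):
                messages.append(f"{rec.image_id}: {label} box {box.as_tuple()} "
                                "outside image bounds")
        for les in rec.boxes("wsl"):
            areas.append(les.area)
            if not any(t.contains(les) for t in teeth):
                messages.append(f"{rec.image_id}: lesion {les.as_tuple()} "
                                "not inside any tooth box")
    if len(areas) >= 200:
        med = float(np.median(areas))
        target = cfg.scaled_area_median
        if abs(med - target) > 0.2 * target:
            messages.append(
                f"lesion-area median {med:.0f} deviates more than 20% from "
                f"configured {target:.0f} (n={len(areas)})")
    return SelfCheckReport(passed=not messages, messages=messages)
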