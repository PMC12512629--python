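"""Axis-aligned bounding-box geometry shared by every other module.

Coordinate convention, fixed package-wide: pixel coordinates are 0-based
and boxes are half-open, ``[x_min, x_max) x [y_min, y_max)``, so the area
of a box is ``(x_max - x_min) * (y_max - y_min)`` and a box drawn around a
``w x h`` image is ``[0, w) x [0, h)``.  Normalized YOLO centre/size
coordinates are converted to this convention at the I/O boundary only
(see :mod:`wsldetect.formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "BoundingBox",
    "Detection",
    "ImageRecord",
    "iou",
    "nms",
]


@dataclass(frozen=True)
class BoundingBox:
    """A strictly positive-area rectangle in some pixel frame.

    The frame (original image, resized image, crop, or tile) is tracked by
    the caller; the box itself is plain geometry.  Coordinates may be
    fractional: rounding to integer pixels happens only where a box is used
    to index a raster.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}) has non-positive extent"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy,
                           self.x_max + dx, self.y_max + dy)

    def clip(self, width: float, height: float) -> "BoundingBox":
        """Clip to ``[0, width) x [0, height)``.

        Raises ``ValueError`` if the box lies entirely outside the frame
        (the clipped rectangle would be degenerate).
        """
        return BoundingBox(
            max(self.x_min, 0.0),
            max(self.y_min, 0.0),
            min(self.x_max, float(width)),
            min(self.y_max, float(height)),
        )

    def intersection(self, other: "BoundingBox") -> float:
        """Intersection area; 0 when disjoint."""
        iw = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        ih = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih

    def contains(self, other: "BoundingBox") -> bool:
        return (self.x_min <= other.x_min and self.y_min <= other.y_min
                and self.x_max >= other.x_max and self.y_max >= other.y_max)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1].

    Both boxes must be valid (the :class:`BoundingBox` constructor already
    rejects zero-area rectangles, so any instance is safe to pass).
    """
    inter = a.intersection(b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class Detection:
    """A detector output: a box, a class label and a confidence score."""

    box: BoundingBox
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def translate(self, dx: float, dy: float) -> "Detection":
        return Detection(self.box.translate(dx, dy), self.label, self.confidence)


@dataclass
class ImageRecord:
    """One dataset image: identifier, dimensions and ground-truth boxes."""

    image_id: str
    width: int
    height: int
    annotations: list[tuple[BoundingBox, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        for box, label in self.annotations:
            if not (0 <= box.x_min and box.x_max <= self.width
                    and 0 <= box.y_min and box.y_max <= self.height):
                raise ValueError(
                    f"annotation {box.as_tuple()} ({label}) outside "
                    f"{self.width}x{self.height} image {self.image_id!r}"
                )

    def boxes(self, label: str) -> list[BoundingBox]:
        return [b for b, lbl in self.annotations if lbl == label]


def nms(dets: Sequence[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression for a single class.

    Detections are visited in order of descending confidence (ties broken
    by smaller input index, so the pass is deterministic); a detection is
    suppressed iff its IoU with an already-kept detection is strictly
    greater than ``iou_threshold``.  The caller partitions detections by
    class; mixing classes here would suppress across classes.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1)")
    if not dets:
        return []
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    kept: list[Detection] = []
    for i in order:
        cand = dets[i]
        if all(iou(cand.box, k.box) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


def nms_by_class(dets: Iterable[Detection], iou_threshold: float) -> list[Detection]:
    """Apply :func:`nms` independently per class label; result sorted by
    descending confidence."""
    by_label: dict[str, list[Detection]] = {}
    for d in dets:
        by_label.setdefault(d.label, []).append(d)
    out: list[Detection] = []
    for label in sorted(by_label):
        out.extend(nms(by_label[label], iou_threshold))
    out.sort(key=lambda d: -d.confidence)
    return out
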