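"""Geometry of the tiled two-stage pipeline.

Four frames appear in the pipeline and every box knows which one it lives
in by construction:

* **original** — the full-resolution photograph (~4000 x 3000 px);
* **resized**  — the photograph proportionally resized to fit a square
  (default 640 x 640), no padding or letterboxing;
* **crop**     — the tooth-union region cut out of the *original* image;
* **tile**     — a fixed-size window (default 640 px, 50 px overlap) cut
  out of the crop at native resolution.

Moving between original and resized is an isotropic rescale
(:func:`rescale_box`); moving between crop/tile and original is a pure
integer translation (:func:`to_original`) because crops and tiles are
taken from the original raster without resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _ski_resize

from .geometry import BoundingBox, ImageRecord

__all__ = [
    "ResizeTransform",
    "TileGrid",
    "proportional_resize",
    "resize_image",
    "union_crop",
    "tile_grid",
    "to_original",
    "rescale_box",
]


def _round_half_up(x: float) -> int:
    """Deterministic half-up rounding (Python's round() is half-even)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ResizeTransform:
    """A single isotropic scale factor between two pixel frames."""

    scale: float
    source_size: tuple[int, int]  # (width, height)
    target_size: tuple[int, int]


def proportional_resize(width: int, height: int, fit: int) -> ResizeTransform:
    """Aspect-preserving resize so that both dimensions fit inside a
    ``fit x fit`` square.

    The scale is ``min(fit/width, fit/height)``; the resized canvas is the
    scaled rectangle itself (no padding).  Upscaling is permitted when both
    dimensions are below ``fit``.
    """
    if width <= 0 or height <= 0 or fit <= 0:
        raise ValueError("width, height and fit must be positive")
    scale = min(fit / width, fit / height)
    target = (_round_half_up(width * scale), _round_half_up(height * scale))
    return ResizeTransform(scale=scale, source_size=(width, height), target_size=target)


def resize_image(image: np.ndarray, transform: ResizeTransform) -> np.ndarray:
    """Resample an image according to a :func:`proportional_resize` transform.

    Bilinear with Gaussian anti-aliasing on downscale (the resampling any
    standard detector front end applies); returns the same dtype as the
    input.
    """
    tw, th = transform.target_size
    if (image.shape[1], image.shape[0]) == (tw, th):
        return image
    out_shape = (th, tw) + image.shape[2:]
    out = _ski_resize(
        image.astype(np.float32), out_shape, order=1,
        anti_aliasing=transform.scale < 1.0, preserve_range=True,
    )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(image.dtype)


def union_crop(tooth_boxes: list[BoundingBox], image: ImageRecord,
               margin: float = 0.0) -> BoundingBox:
    """Minimal rectangle containing all tooth boxes, expanded by ``margin``
    px on every side and clipped to the image bounds."""
    if not tooth_boxes:
        raise ValueError("union_crop requires at least one tooth box")
    x0 = min(b.x_min for b in tooth_boxes) - margin
    y0 = min(b.y_min for b in tooth_boxes) - margin
    x1 = max(b.x_max for b in tooth_boxes) + margin
    y1 = max(b.y_max for b in tooth_boxes) + margin
    return BoundingBox(x0, y0, x1, y1).clip(image.width, image.height)


def _axis_offsets(dim: int, window: int, stride: int) -> list[int]:
    if dim <= window:
        return [0]
    offsets = []
    x = 0
    while x + window <= dim:
        offsets.append(x)
        x += stride
    if offsets[-1] + window < dim:
        offsets.append(dim - window)  # clamp last tile to the far edge
    return offsets


@dataclass(frozen=True)
class TileGrid:
    """Ordered (row-major) offsets of overlapping windows covering a crop."""

    window: int
    overlap: int
    crop_size: tuple[int, int]        # (width, height)
    x_offsets: tuple[int, ...]
    y_offsets: tuple[int, ...]

    @property
    def stride(self) -> int:
        return self.window - self.overlap

    @property
    def tile_size(self) -> tuple[int, int]:
        """(width, height) of every tile; clamped to the crop when the
        crop is smaller than the window along an axis."""
        return (min(self.window, self.crop_size[0]),
                min(self.window, self.crop_size[1]))

    @property
    def offsets(self) -> list[tuple[int, int]]:
        """Row-major (x, y) tile origins."""
        return [(x, y) for y in self.y_offsets for x in self.x_offsets]

    def __len__(self) -> int:
        return len(self.x_offsets) * len(self.y_offsets)


def tile_grid(crop_width: int, crop_height: int, window: int = 640,
              overlap: int = 50) -> TileGrid:
    """Sliding-window grid over a crop.

    Offsets along each axis are ``0, stride, 2*stride, ...`` while the
    window still fits; if the last regular tile does not reach the edge, a
    final tile clamped to ``dim - window`` is appended so coverage is
    complete.  An axis no longer than the window gets the single offset 0
    with the tile clamped to the axis extent.

    Any axis-aligned object with both sides <= ``overlap`` is guaranteed to
    fall entirely inside at least one tile, whatever its position — the
    reason overlapping windows are used at all.
    """
    if not (window > overlap >= 0):
        raise ValueError(f"need window > overlap >= 0, got {window}, {overlap}")
    if crop_width <= 0 or crop_height <= 0:
        raise ValueError("crop dimensions must be positive")
    stride = window - overlap
    return TileGrid(
        window=window,
        overlap=overlap,
        crop_size=(crop_width, crop_height),
        x_offsets=tuple(_axis_offsets(crop_width, window, stride)),
        y_offsets=tuple(_axis_offsets(crop_height, window, stride)),
    )


def to_original(box: BoundingBox, tile_origin: tuple[float, float] = (0, 0),
                crop_origin: tuple[float, float] = (0, 0)) -> BoundingBox:
    """Map a box from tile frame to the original image frame.

    Tiles are cut from the original raster, so the mapping is an exact
    translation by the tile origin (within the crop) plus the crop origin
    (within the original image).  Pass ``tile_origin=(0, 0)`` for a box
    already in the crop frame.
    """
    dx = tile_origin[0] + crop_origin[0]
    dy = tile_origin[1] + crop_origin[1]
    return box.translate(dx, dy)


def rescale_box(box: BoundingBox, transform: ResizeTransform,
                direction: str = "forward") -> BoundingBox:
    """Move a box across a :class:`ResizeTransform`.

    ``forward`` maps source-frame to target-frame coordinates (multiply by
    the scale); ``inverse`` maps back (divide).  Coordinates stay
    fractional — integer pixels are taken only where a raster is indexed —
    so the forward-then-inverse round trip is exact to float precision.
    The result is clipped to the destination frame bounds; a box lying
    entirely outside the destination frame raises ``ValueError``.
    """
    if direction == "forward":
        s = transform.scale
        # clip against the exact scaled extent (the integer canvas rounds
        # it by up to half a pixel; clipping there would break round trips)
        bound_w = transform.source_size[0] * s
        bound_h = transform.source_size[1] * s
    elif direction == "inverse":
        s = 1.0 / transform.scale
        bound_w, bound_h = transform.source_size
    else:
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    x0 = box.x_min * s
    y0 = box.y_min * s
    x1 = box.x_max * s
    y1 = box.y_max * s
    x1 = min(x1, float(bound_w))
    y1 = min(y1, float(bound_h))
    x0 = max(x0, 0.0)
    y0 = max(y0, 0.0)
    return BoundingBox(x0, y0, x1, y1)
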