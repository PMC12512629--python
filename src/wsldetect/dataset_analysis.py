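"""Dataset-geometry analyses.

Where do lesions sit in the photographs and on the teeth, how big are
their boxes, and what does whole-image downscaling do to the COCO size
class of those boxes?  These are the analyses that motivate tiled
detection in the first place: the median lesion box (~2900 px of area at
full resolution) drops below the COCO small-object boundary (1024 px =
32^2) once a ~4000 x 3000 photograph is squeezed into a 640 px square.

All coverage computations use bounding-box geometry — the only geometry
annotations provide; pixel-accurate crown outlines are not available and
this is a stated limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from shapely.geometry import box as _shapely_box
from shapely.ops import unary_union

from .geometry import BoundingBox
from .slicing import ResizeTransform

__all__ = [
    "SizeStats",
    "Heatmap",
    "COCO_SMALL_MAX",
    "COCO_MEDIUM_MAX",
    "coco_size_class",
    "area_stats",
    "downscale_shift",
    "chi_square_2x2",
    "absolute_heatmap",
    "relative_heatmap",
    "crown_coverage",
]

# COCO size-class boundaries (areas in px): small < 32^2, medium < 96^2
COCO_SMALL_MAX = 1024.0
COCO_MEDIUM_MAX = 9216.0


def coco_size_class(area: float) -> str:
    if area < COCO_SMALL_MAX:
        return "small"
    if area < COCO_MEDIUM_MAX:
        return "medium"
    return "large"


@dataclass(frozen=True)
class SizeStats:
    """Median/IQR of box areas plus COCO size-class counts."""

    n: int
    median: float
    q1: float
    q3: float
    n_small: int
    n_medium: int
    n_large: int

    @property
    def small_fraction(self) -> float:
        return self.n_small / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return {"n": self.n, "median": self.median, "q1": self.q1, "q3": self.q3,
                "small": self.n_small, "medium": self.n_medium,
                "large": self.n_large}


def _areas(boxes: Iterable[BoundingBox | float]) -> np.ndarray:
    vals = [b.area if isinstance(b, BoundingBox) else float(b) for b in boxes]
    return np.asarray(vals, dtype=float)


def area_stats(boxes: Sequence[BoundingBox | float]) -> SizeStats:
    """Median and IQR of box areas (linear-interpolation quantiles,
    numpy's default, a.k.a. type 7) plus COCO size-class counts.

    Accepts boxes or raw areas.
    """
    areas = _areas(boxes)
    if areas.size == 0:
        raise ValueError("area_stats requires at least one box")
    q1, med, q3 = np.percentile(areas, [25, 50, 75])
    return SizeStats(
        n=int(areas.size), median=float(med), q1=float(q1), q3=float(q3),
        n_small=int(np.count_nonzero(areas < COCO_SMALL_MAX)),
        n_medium=int(np.count_nonzero((areas >= COCO_SMALL_MAX)
                                      & (areas < COCO_MEDIUM_MAX))),
        n_large=int(np.count_nonzero(areas >= COCO_MEDIUM_MAX)),
    )


def downscale_shift(boxes: Sequence[BoundingBox | float],
                    transform: ResizeTransform) -> tuple[SizeStats, SizeStats]:
    """Size statistics before and after an isotropic resize.

    Areas are multiplied by ``scale**2``; under any scale < 1 the
    proportion of small-class boxes can only grow.
    """
    areas = _areas(boxes)
    return area_stats(list(areas)), area_stats(list(areas * transform.scale**2))


def chi_square_2x2(table: np.ndarray | Sequence[Sequence[float]],
                   ) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 contingency table, no continuity
    correction, 1 degree of freedom.

    Returns ``(statistic, p_value)``; any zero expected count is an
    error (the statistic is undefined there).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    n = obs.sum()
    if n == 0:
        raise ValueError("empty table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected <= 0).any():
        raise ValueError("zero expected count; chi-square undefined")
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(_stats.chi2.sf(stat, df=1))
    return stat, p


@dataclass
class Heatmap:
    """Accumulated box-coverage grid over a normalized frame."""

    values: np.ndarray   # (grid, grid), non-negative
    frame: str           # "image" (normalized [0,1]^2) or "tooth" (unit square)
    n_boxes: int = 0
    n_dropped: int = 0   # lesions assignable to no tooth (tooth frame only)

    @property
    def normalized(self) -> np.ndarray:
        """Values scaled so the maximum is 1 (for rendering); all-zero
        grids are returned unchanged."""
        m = self.values.max()
        return self.values / m if m > 0 else self.values


def _accumulate(grid: np.ndarray, x0: float, y0: float, x1: float, y1: float) -> None:
    """Add a unit-intensity rectangle (coords in [0,1]) to the grid with
    exact fractional cell coverage (coverage measured in cell areas)."""
    g = grid.shape[0]
    edges = np.linspace(0.0, 1.0, g + 1)
    ox = np.clip(np.minimum(edges[1:], x1) - np.maximum(edges[:-1], x0), 0.0, None)
    oy = np.clip(np.minimum(edges[1:], y1) - np.maximum(edges[:-1], y0), 0.0, None)
    cell = 1.0 / g
    grid += np.outer(oy / cell, ox / cell)


def absolute_heatmap(boxes: Sequence[BoundingBox],
                     dims: Sequence[tuple[int, int]],
                     grid_size: int = 64) -> Heatmap:
    """Accumulate boxes over the dataset in each image's normalized
    [0,1]^2 frame.

    ``dims[i]`` is the (width, height) of the image box ``i`` comes from.
    Each box contributes its exact fractional coverage per grid cell, so
    the total accumulated mass equals the sum of normalized box areas
    times the number of cells.
    """
    if len(boxes) != len(dims):
        raise ValueError("boxes and dims must be parallel sequences")
    grid = np.zeros((grid_size, grid_size), dtype=float)
    for b, (w, h) in zip(boxes, dims):
        _accumulate(grid, b.x_min / w, b.y_min / h, b.x_max / w, b.y_max / h)
    return Heatmap(values=grid, frame="image", n_boxes=len(boxes))


def assign_to_tooth(lesion: BoundingBox,
                    teeth: Sequence[BoundingBox]) -> int | None:
    """Index of the tooth box with maximal intersection area with the
    lesion, or None when the lesion is disjoint from every tooth.

    Max intersection area — not max IoU — because a small lesion inside a
    large tooth has near-zero IoU with every tooth.
    """
    best, best_area = None, 0.0
    for j, t in enumerate(teeth):
        a = lesion.intersection(t)
        if a > best_area:
            best, best_area = j, a
    return best


def relative_heatmap(lesions: Sequence[BoundingBox],
                     teeth: Sequence[BoundingBox],
                     grid_size: int = 64) -> Heatmap:
    """Accumulate each lesion box in its host tooth's unit square.

    Each lesion is assigned to the tooth with maximal intersection area
    (lesions touching no tooth are dropped and counted), its box is
    expressed in tooth-relative coordinates
    ``(x - tooth_x_min) / tooth_width`` (clipped to [0,1]) and rasterized
    with fractional cell coverage.  With gum-adjacent lesions the mass
    concentrates in the gingival (top/bottom) band of the unit square.
    """
    grid = np.zeros((grid_size, grid_size), dtype=float)
    dropped = 0
    for les in lesions:
        j = assign_to_tooth(les, teeth)
        if j is None:
            dropped += 1
            continue
        t = teeth[j]
        x0 = np.clip((les.x_min - t.x_min) / t.width, 0.0, 1.0)
        x1 = np.clip((les.x_max - t.x_min) / t.width, 0.0, 1.0)
        y0 = np.clip((les.y_min - t.y_min) / t.height, 0.0, 1.0)
        y1 = np.clip((les.y_max - t.y_min) / t.height, 0.0, 1.0)
        if x1 > x0 and y1 > y0:
            _accumulate(grid, x0, y0, x1, y1)
    return Heatmap(values=grid, frame="tooth",
                   n_boxes=len(lesions) - dropped, n_dropped=dropped)


def peripheral_mass_fraction(heatmap: Heatmap, band: float = 0.25) -> float:
    """Fraction of heatmap mass in the outer ``band`` border of the unit
    square (the peri-gingival band lives in the top/bottom part of it)."""
    g = heatmap.values.shape[0]
    k = int(round(g * band))
    total = heatmap.values.sum()
    if total == 0:
        return 0.0
    inner = heatmap.values[k:g - k, k:g - k].sum()
    return float((total - inner) / total)


def crown_coverage(lesions: Sequence[BoundingBox], tooth: BoundingBox) -> float:
    """Fraction of the tooth-crown box covered by the union of its lesion
    boxes (each clipped to the tooth), in [0, 1].

    Exact rectangle-union area (overlapping lesions are counted once).
    """
    polys = []
    for les in lesions:
        inter = les.intersection(tooth)
        if inter == 0.0:
            continue
        polys.append(_shapely_box(max(les.x_min, tooth.x_min),
                                  max(les.y_min, tooth.y_min),
                                  min(les.x_max, tooth.x_max),
                                  min(les.y_max, tooth.y_max)))
    if not polys:
        return 0.0
    return float(unary_union(polys).area / tooth.area)
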