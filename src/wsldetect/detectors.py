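"""Pluggable detector backends.

The pipeline is detector-agnostic: any object with a ``detect(image)``
method returning :class:`~wsldetect.geometry.Detection` lists satisfies the
contract, and a deep-learning backend (e.g. a YOLO-family network) can be
plugged in without touching the pipeline.  The package bundles a classical
brightness-blob detector so the whole toolchain runs end-to-end with no
trained weights, plus a hand-specified activation backend used by the
score-CAM tests.

The blob detector's confidence (mean saliency of the component's pixels)
is a plumbing heuristic, not a calibrated probability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening as _morph_opening

from .geometry import BoundingBox, Detection

__all__ = [
    "Detector",
    "BlobDetectorConfig",
    "BlobDetector",
    "toy_activations",
    "HalfPlaneBackend",
    "build_detector",
    "lesion_blob_config",
    "tooth_blob_config",
]


@runtime_checkable
class Detector(Protocol):
    """Structural contract every detector backend satisfies.

    ``detect`` must be deterministic for a fixed image and configuration
    and return boxes lying within the presented image's bounds.
    """

    label: str

    def detect(self, image: np.ndarray) -> list[Detection]: ...


@dataclass(frozen=True)
class BlobDetectorConfig:
    """Configuration for the classical brightness-blob detector.

    Areas are in pixels of whatever frame the detector is shown (a tile,
    a resized image, ...); :meth:`scaled` rescales the area limits when a
    config tuned at one resolution is reused at another.
    """

    label: str = "wsl"
    channel_weights: tuple[float, float, float] = (0.299, 0.587, 0.114)
    threshold: float = 0.78          # saliency in (0, 1)
    min_area: float = 60.0           # connected-component pixel count
    max_area: float = 5.0e4
    opening_radius: int = 2          # disk radius, px; 0 disables

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold {self.threshold} outside (0, 1)")
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")

    def scaled(self, linear_scale: float) -> "BlobDetectorConfig":
        """Adapt the config to images whose linear dimensions are
        ``linear_scale`` times the ones it was tuned for (areas scale with
        the square; the opening footprint with the linear factor)."""
        return replace(
            self,
            min_area=self.min_area * linear_scale**2,
            max_area=self.max_area * linear_scale**2,
            opening_radius=max(1, round(self.opening_radius * linear_scale))
            if self.opening_radius else 0,
        )


def lesion_blob_config(linear_scale: float = 1.0) -> BlobDetectorConfig:
    """Blob config tuned for lesion blobs at full photograph resolution
    (~4000 x 3000); pass the linear scale of smaller presets."""
    return BlobDetectorConfig(label="wsl", threshold=0.78, min_area=60.0,
                              max_area=5.0e4, opening_radius=2).scaled(linear_scale)


def tooth_blob_config() -> BlobDetectorConfig:
    """Blob config tuned for tooth shapes on the 640-fit resized image.

    The tooth stage always sees a 640-fit frame, so this config is
    resolution-free with respect to the source photograph.
    """
    return BlobDetectorConfig(label="tooth", threshold=0.55, min_area=500.0,
                              max_area=2.0e5, opening_radius=1)


class BlobDetector:
    """Threshold -> morphological opening -> connected components.

    Saliency is the channel-weighted brightness normalized to [0, 1];
    pixels above the threshold are grouped with 8-connectivity, components
    outside the area limits are dropped, and each surviving component
    yields one detection whose box is the component's bounding box and
    whose confidence is the mean saliency over the component's pixels
    (capped at 1).  Fully deterministic.
    """

    def __init__(self, config: BlobDetectorConfig | None = None):
        self.config = config or BlobDetectorConfig()
        self.label = self.config.label

    def saliency(self, image: np.ndarray) -> np.ndarray:
        if image.size == 0 or image.ndim not in (2, 3):
            raise ValueError("image must be a non-empty 2D or 3D raster")
        img = image.astype(np.float32)
        if np.issubdtype(image.dtype, np.integer):
            img /= float(np.iinfo(image.dtype).max)
        if img.ndim == 3:
            w = np.asarray(self.config.channel_weights, dtype=np.float32)
            w = w / w.sum()
            sal = img[..., : len(w)] @ w
        else:
            sal = img
        return np.clip(sal, 0.0, 1.0)

    def detect(self, image: np.ndarray) -> list[Detection]:
        cfg = self.config
        sal = self.saliency(image)
        mask = sal > cfg.threshold
        if cfg.opening_radius > 0 and mask.any():
            mask = _morph_opening(mask, disk(cfg.opening_radius))
        if not mask.any():
            return []
        labelled = cc_label(mask, connectivity=2)
        dets: list[Detection] = []
        for region in regionprops(labelled):
            if not (cfg.min_area <= region.area <= cfg.max_area):
                continue
            r0, c0, r1, c1 = region.bbox   # half-open, matching our convention
            rr, cc = region.coords[:, 0], region.coords[:, 1]
            conf = float(min(1.0, sal[rr, cc].mean()))
            dets.append(Detection(BoundingBox(c0, r0, c1, r1), cfg.label, conf))
        dets.sort(key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min))
        return dets


def toy_activations(image: np.ndarray, n_channels: int) -> list[np.ndarray]:
    """Hand-specified activation maps for explainability tests.

    ``n_channels`` vertical-band indicator maps at the image's spatial
    resolution: channel k is 1 on the k-th of ``n_channels`` equal-width
    vertical bands and 0 elsewhere (for ``n_channels=2``: left-half and
    right-half indicators).  Values are in [0, 1] by construction.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    h, w = image.shape[:2]
    maps = []
    edges = np.linspace(0, w, n_channels + 1)
    cols = np.arange(w)
    for k in range(n_channels):
        m = np.zeros((h, w), dtype=np.float64)
        m[:, (cols >= edges[k]) & (cols < edges[k + 1])] = 1.0
        maps.append(m)
    return maps


class HalfPlaneBackend:
    """Backend exposing :func:`toy_activations`; optionally wraps another
    detector so score-CAM target scores can query detections."""

    def __init__(self, n_channels: int = 2, detector: Detector | None = None):
        self.n_channels = n_channels
        self._detector = detector
        self.label = detector.label if detector is not None else "wsl"

    def activations(self, image: np.ndarray) -> list[np.ndarray]:
        return toy_activations(image, self.n_channels)

    def detect(self, image: np.ndarray) -> list[Detection]:
        if self._detector is None:
            return []
        return self._detector.detect(image)


_REGISTRY = {
    "blob": lambda params: BlobDetector(BlobDetectorConfig(**params)),
}


def build_detector(spec: str | dict) -> Detector:
    """Build a detector from a config entry.

    Accepts ``{"backend": "blob", ...params}`` or the shorthand string
    ``"blob"`` (default parameters).  Registry keyed by backend name so
    external backends can be added with :func:`register_backend`.
    """
    if isinstance(spec, str):
        name, params = spec, {}
    else:
        params = dict(spec)
        name = params.pop("backend", "blob")
    if name not in _REGISTRY:
        raise KeyError(f"unknown detector backend {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name](params)


def register_backend(name: str, factory) -> None:
    _REGISTRY[name] = factory
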