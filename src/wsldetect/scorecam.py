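"""Gradient-free score-CAM explainability.

Score-CAM weights a backend's activation channels by how much the target
score responds when the input is masked by each (normalized, upsampled)
channel, then combines the channels into a saliency map.  Because no
gradients are involved, it works against the detector contract alone —
any backend exposing ``activations(image)`` can be explained, including
ones whose internals are opaque.

For detection the interesting target is not only the confidence: to ask
*where the model looks when it draws boxes well*, the target score can be
the maximum IoU between the detections on the masked image and a
reference annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.transform import resize as _ski_resize

from .geometry import BoundingBox, Detection, iou

__all__ = [
    "CamBackend",
    "CamConfig",
    "score_cam",
    "confidence_score",
    "iou_score",
    "render_overlay",
]


@runtime_checkable
class CamBackend(Protocol):
    def activations(self, image: np.ndarray) -> Sequence[np.ndarray]: ...


@dataclass
class CamConfig:
    """Score-CAM knobs: the target score and output normalization."""

    score: Callable[[np.ndarray], float] = field(default=None)  # type: ignore[assignment]
    normalize_output: bool = False  # min-max scale the CAM before return

    def __post_init__(self) -> None:
        if self.score is None:
            self.score = lambda img: float(np.asarray(img, dtype=float).mean())


def confidence_score(detector) -> Callable[[np.ndarray], float]:
    """Target score: highest detection confidence on the (masked) image;
    0 when nothing is detected."""

    def score(image: np.ndarray) -> float:
        dets = detector.detect(image)
        return max((d.confidence for d in dets), default=0.0)

    return score


def iou_score(detector, reference: Sequence[BoundingBox],
              ) -> Callable[[np.ndarray], float]:
    """Target score: maximum IoU between any detection on the (masked)
    image and any reference annotation box; 0 when nothing is detected.

    This is the localization-quality target: the CAM then highlights the
    regions whose visibility lets the model draw boxes that agree with
    the annotator.
    """
    ref = list(reference)

    def score(image: np.ndarray) -> float:
        dets = detector.detect(image)
        if not dets or not ref:
            return 0.0
        return max(iou(d.box, g) for d in dets for g in ref)

    return score


def _normalize_map(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi > lo:
        return (a - lo) / (hi - lo)
    # constant channel: all-zero map (an all-zero channel stays zero and
    # a flat channel carries no spatial information either way)
    return np.zeros_like(a, dtype=float)


def score_cam(backend: CamBackend, image: np.ndarray,
              cfg: CamConfig | None = None) -> np.ndarray:
    """Compute the score-CAM saliency map at the image's resolution.

    Per channel: min-max normalize the activation map to [0, 1], upsample
    bilinearly to the image size, soft-mask the image by elementwise
    product (all color channels), and evaluate the target score.  Channel
    weights are the softmax of the score increases over the unmasked
    baseline (a shared shift, so identical increases give uniform
    weights); the CAM is the rectified weighted sum of the upsampled
    normalized maps — non-negative everywhere and exactly 0 wherever all
    activations are 0.
    """
    cfg = cfg or CamConfig()
    if not hasattr(backend, "activations"):
        raise TypeError(f"backend {type(backend).__name__} exposes no activations()")
    maps = list(backend.activations(image))
    if not maps:
        raise ValueError("backend returned no activation channels")
    h, w = image.shape[:2]
    img = np.asarray(image, dtype=float)

    upsampled = []
    for m in maps:
        m = np.asarray(m, dtype=float)
        norm = _normalize_map(m)
        if norm.shape != (h, w):
            norm = _ski_resize(norm, (h, w), order=1, preserve_range=True,
                               anti_aliasing=False)
        upsampled.append(np.clip(norm, 0.0, 1.0))

    baseline = cfg.score(image)
    increases = np.empty(len(upsampled))
    for k, mask in enumerate(upsampled):
        masked = img * (mask[..., None] if img.ndim == 3 else mask)
        masked = masked.astype(image.dtype) if np.issubdtype(
            image.dtype, np.integer) else masked
        increases[k] = cfg.score(masked) - baseline

    # softmax over score increases (shift-invariant, so subtracting the
    # baseline changes nothing numerically but documents the intent)
    z = increases - increases.max()
    weights = np.exp(z)
    weights /= weights.sum()

    cam = np.zeros((h, w), dtype=float)
    for wk, mask in zip(weights, upsampled):
        cam += wk * mask
    cam = np.maximum(cam, 0.0)
    if cfg.normalize_output:
        top = cam.max()
        if top > 0:
            cam = cam / top
    return cam


def render_overlay(image: np.ndarray, cam: np.ndarray, alpha: float = 0.5,
                   cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a colormapped CAM onto the image (uint8 RGB out).

    Purely cosmetic: the CAM is min-max scaled for display only.
    """
    import matplotlib

    top = cam.max()
    disp = cam / top if top > 0 else cam
    colors = matplotlib.colormaps[cmap](disp)[..., :3]  # drop alpha channel
    img = np.asarray(image, dtype=float)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        img = img / 255.0
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    blend = (1 - alpha) * img + alpha * colors
    return np.clip(blend * 255.0, 0, 255).astype(np.uint8)
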