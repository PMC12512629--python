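"""Shared fixtures: small synthetic presets and matching detectors.

The 1600 x 1200 preset is a geometrically faithful miniature of the full
4000 x 3000 canvas (linear scale 0.4); detector area limits are scaled
accordingly via ``BlobDetectorConfig.scaled``.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wsldetect.detectors import BlobDetector, lesion_blob_config, tooth_blob_config
from wsldetect.geometry import BoundingBox, Detection
from wsldetect.synthetic import GeneratorConfig, generate_image


@pytest.fixture(scope="session")
def preset_cfg() -> GeneratorConfig:
    return GeneratorConfig().preset(1600, 1200)


@pytest.fixture(scope="session")
def preset_scale(preset_cfg) -> float:
    return preset_cfg.linear_scale


@pytest.fixture(scope="session")
def tooth_detector() -> BlobDetector:
    return BlobDetector(tooth_blob_config())


@pytest.fixture(scope="session")
def lesion_detector_preset(preset_scale) -> BlobDetector:
    return BlobDetector(lesion_blob_config(preset_scale))


@pytest.fixture(scope="session")
def preset_sample(preset_cfg):
    """One deterministic preset image with its ground-truth record."""
    rng = np.random.default_rng(20240501)
    return generate_image(preset_cfg, rng, image_id="sample")


def box(x0, y0, x1, y1) -> BoundingBox:
    return BoundingBox(x0, y0, x1, y1)


def det(x0, y0, x1, y1, conf, label="wsl") -> Detection:
    return Detection(BoundingBox(x0, y0, x1, y1), label, conf)
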