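"""Shared fixtures: small simulated images and ROI builders.

Heavy simulated images are session-scoped so the suite renders each
only once.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibremorph.segmentation import ROI, LabelMap, labels_to_rois
from fibremorph.synthetic import IntensityModel, simulate_image


@pytest.fixture(scope="session")
def noiseless_model() -> IntensityModel:
    return IntensityModel(noise_sd=0.0, blur_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_model):
    """Noise- and blur-free 512 px simulated image with ground truth."""
    return simulate_image(512, 512, slow_fraction=0.3, hybrid_fraction=0.05,
                          pixel_size=1.0, model=noiseless_model, seed=11)


@pytest.fixture(scope="session")
def default_sim():
    """Default-noise 512 px simulated image with ground truth."""
    return simulate_image(512, 512, slow_fraction=0.35, hybrid_fraction=0.05,
                          pixel_size=1.0, seed=13)


def roi_from_mask(mask: np.ndarray, pixel_size: float = 1.0) -> ROI:
    """Build a single ROI from a full-image boolean mask."""
    labels = LabelMap(mask.astype(np.int32))
    rois = labels_to_rois(labels, pixel_size)
    assert len(rois) == 1, "mask must hold exactly one connected region"
    return rois[0]


@pytest.fixture
def make_roi():
    return roi_from_mask
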