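"""Shared fixtures: seeded images and a screened synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from fundus_screen import generate_cohort, screen_image
from fundus_screen.synthetic import SyntheticSpec, generate

COHORT_SIZE = 200
COHORT_SEED = 20260923


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def smooth_image(rng) -> np.ndarray:
    """A spatially smooth mid-range grey image (no impulse noise)."""
    from scipy import ndimage

    base = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (120, 160)), 6.0)
    base = 110 + 60 * base / np.abs(base).max()
    return np.clip(base, 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def clean_image_and_truth():
    """One clean 600x900 fundus image with the macula planted 2 DD along
    the horizontal."""
    spec = SyntheticSpec(seed=42, noise_density=0.01)
    return generate(spec)


@pytest.fixture(scope="session")
def screened_cohort():
    """A 200-image half-positive synthetic cohort, each image screened by the
    full pipeline.  Session-scoped: this is the expensive shared input for the
    planted-truth recovery and classification checks."""
    images, truths = generate_cohort(COHORT_SIZE, 0.5, seed=COHORT_SEED)
    results = [screen_image(img) for img in images]
    return images, truths, results
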