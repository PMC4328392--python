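"""Shared fixtures: a small synthetic section reused across test modules."""

import numpy as np
import pytest

from fiberlayer.synthetic import SectionGeometry, generate_section


@pytest.fixture(scope="session")
def small_geometry() -> SectionGeometry:
    """Default layer radii at a coarse 1 px/μm calibration (fast)."""
    return SectionGeometry(layer_radii_um=(250.0, 430.0, 610.0), resolution=1.0)


@pytest.fixture(scope="session")
def small_section(small_geometry):
    """(LayerMask, nuclei CalibratedImage) for the small geometry."""
    return generate_section(small_geometry, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
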