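"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from radrobust.features import ExtractionConfig
from radrobust.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def iso_ball_spec():
    """10 mm-radius spherical tumor on an isotropic 1 mm grid, no noise."""
    return PhantomSpec(
        grid_shape=(40, 40, 40),
        spacing_mm=(1.0, 1.0, 1.0),
        tumor_axes_mm=(10.0, 10.0, 10.0),
        noise_sigma_hu=0.0,
        texture_amplitude_hu=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def iso_ball(iso_ball_spec):
    return generate_phantom(iso_ball_spec)


@pytest.fixture(scope="session")
def textured_phantom():
    """Default-geometry phantom with texture and noise (anisotropic 3x1x1 mm)."""
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def quiet_phantom():
    """Textured but noise-free phantom for interpolation-sensitive checks."""
    return generate_phantom(
        PhantomSpec(noise_sigma_hu=0.0, texture_amplitude_hu=10.0, seed=5)
    )


@pytest.fixture(scope="session")
def cheap_config():
    """Shape + first-order on the unfiltered image only (fast extraction)."""
    return ExtractionConfig(
        enabled_classes=("shape", "firstorder"), image_types=("original",)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
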