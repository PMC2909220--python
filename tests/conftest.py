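import numpy as np
import pytest

from colonygrid import FORMAT_384, partition
from colonygrid.synthplate import PlateSpec, generate_plate


@pytest.fixture(scope="session")
def clean_plate():
    """Seeded clean 384 plate (margin 0: image == grid layout box)."""
    spec = PlateSpec(seed=1, noise_sd=2.0, margin=0)
    img, truth = generate_plate(spec)
    return img, truth


@pytest.fixture(scope="session")
def clean_plate_grid(clean_plate):
    img, _ = clean_plate
    return partition(img, FORMAT_384)


@pytest.fixture(scope="session")
def rough_plate():
    """Clean 384 plate with a margin around the grid (a rough crop)."""
    spec = PlateSpec(seed=3, noise_sd=2.0)
    return generate_plate(spec)


def make_rotated(theta: float, seed: int = 2):
    spec = PlateSpec(seed=seed, rotation=theta, noise_sd=2.0)
    img, truth = generate_plate(spec)
    return img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
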