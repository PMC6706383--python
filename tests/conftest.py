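import numpy as np
import pytest

from forestfrag import BinaryRaster, make_primitive


@pytest.fixture
def single_pixel_64():
    return make_primitive("single_pixel", (64, 64))


@pytest.fixture
def h_line_101():
    return make_primitive("h_line", (101, 101))


@pytest.fixture
def filled_101():
    return make_primitive("filled_rect", (101, 101))


@pytest.fixture
def filled_256():
    return make_primitive("filled_rect", (256, 256))


def random_mask(shape, density, seed):
    rng = np.random.default_rng(seed)
    return BinaryRaster((rng.random(shape) < density).astype(np.uint8))


@pytest.fixture
def random_masks_32():
    """Small random masks for oracle-equivalence checks."""
    return [random_mask((32, 32), d, s) for s, d in enumerate((0.1, 0.3, 0.5, 0.8))]
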