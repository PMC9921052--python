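import numpy as np
import pytest

from spotrecon import PixelSpot


@pytest.fixture
def rng():
    return np.random.default_rng(20230121)


def random_spot(rng, shape, density=0.5):
    return PixelSpot(rng.random(shape) < density)


@pytest.fixture
def rect_factory():
    """Rectangles on a small grid, handy for constructing known relations."""

    def make(shape, r0, c0, r1, c1):
        m = np.zeros(shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        return PixelSpot(m)

    return make
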