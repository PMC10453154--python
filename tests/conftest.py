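import numpy as np
import pytest

from gdfuse.image_io import ImageRaster, ImageStack
from gdfuse.synthetic import FixtureSpec, make_stack


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_pair_16(rng):
    """A 16x16 two-image stack of seeded random planes."""
    a = ImageRaster(rng.random((16, 16)))
    b = ImageRaster(rng.random((16, 16)))
    return ImageStack((a, b))


@pytest.fixture
def multifocus_stack():
    """Seeded 128x128 complementary-blur pair with ground truth and masks."""
    return make_stack(FixtureSpec(scenario="multifocus", seed=7))


@pytest.fixture
def small_multifocus_stack():
    """64x64 variant for optimizer tests."""
    return make_stack(FixtureSpec(scenario="multifocus", size=(64, 64), seed=11))
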