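import numpy as np
import pytest

from cyanocount.io import MonoImage, RunConfig


@pytest.fixture
def config():
    return RunConfig(um_per_pixel=0.645)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(pixels, bit_depth=8, um_per_pixel=1.0):
    return MonoImage(np.asarray(pixels), bit_depth, um_per_pixel, "test")


@pytest.fixture
def mono_factory():
    return make_image
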