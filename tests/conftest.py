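import numpy as np
import pytest

from stsal import Image, STConfig, make_popout_image

WORKING = (170, 128)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return STConfig()


@pytest.fixture
def blank_fixture():
    return make_popout_image("blank", WORKING, seed=0)


@pytest.fixture
def edge_fixture():
    return make_popout_image("edge", WORKING, seed=3)


@pytest.fixture
def crossing_fixture():
    return make_popout_image("crossing", WORKING, seed=3)


@pytest.fixture
def color_fixture():
    return make_popout_image("color_popout", WORKING, seed=3)


@pytest.fixture
def random_image(rng):
    return Image(rng.uniform(0, 1, (16, 16, 3)))
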