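import numpy as np
import pytest

from trapmatch.synthetic_scenes import InsectSpec, make_template

# Half-scale setup used by the faster detection tests.
SMALL_TEMPLATE_SIZE = (100, 72)
SMALL_SCALE = 0.5
SMALL_FRAME = (640, 480)


@pytest.fixture(scope="session")
def full_template() -> np.ndarray:
    """Canonical 200x144 mosquito template at scale 1."""
    return make_template()


@pytest.fixture(scope="session")
def small_template() -> np.ndarray:
    """Half-scale 100x72 template for fast batch tests."""
    return make_template(InsectSpec("mosquito", (0, 0), scale=SMALL_SCALE),
                         template_size=SMALL_TEMPLATE_SIZE)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
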