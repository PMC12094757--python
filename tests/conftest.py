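import sys
from pathlib import Path

import numpy as np
import pytest

# make the scalar oracle helpers importable from every test module
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A small random grayscale image in [0, 255]."""
    return rng.uniform(0.0, 255.0, size=(16, 16))


@pytest.fixture
def default_phantom():
    from fracim.phantoms import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(seed=0))
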