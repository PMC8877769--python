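import numpy as np
import pytest

from fetalhc.phantoms import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free phantom settings: sharp band, no gaps, no speckle."""
    return PhantomConfig(noise=False, gap_fraction=0.0)
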