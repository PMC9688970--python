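import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noise_image(rng):
    """Raw uniform [0,1) three-channel image, the generic small fixture."""
    return rng.random((10, 10, 3))
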