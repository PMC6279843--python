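import numpy as np
import pytest

from aprep.cells import APRDomain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def domain_1d8():
    """The didactic 1D domain: 8 pixels, omega=8, levels 1..3."""
    return APRDomain((8,))
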