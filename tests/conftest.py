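import numpy as np
import pytest

from alloscope.structure import pi3k_domain_map
from alloscope.synthetic import four_block_preset, generate, pi3k_like_preset


@pytest.fixture(scope="session")
def preset_system():
    """The PI3Kalpha-like detachment preset (1000 frames, 1 ns spacing)."""
    return generate(pi3k_like_preset())


@pytest.fixture(scope="session")
def preset_map():
    return pi3k_domain_map()


@pytest.fixture(scope="session")
def four_block_system():
    """Planted 4-block benchmark (10^4 frames)."""
    return generate(four_block_preset())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
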