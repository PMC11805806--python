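import numpy as np
import pytest

import lvig as lv


@pytest.fixture
def rps3_system():
    """3-species rock-paper-scissors with d=-0.5 and unit growth rates."""
    return lv.rps3(-0.5)


@pytest.fixture
def rpsls5_system():
    """5-species RPSLS with d=-0.5 and unit growth rates."""
    return lv.rpsls5(-0.5)


@pytest.fixture
def cycle4_system():
    """4-species mixed-dimension cycle matrix with d=-0.5."""
    return lv.cycle4(-0.5)


@pytest.fixture
def rps3_catalog(rps3_system):
    a, b = rps3_system
    return lv.enumerate_admissible(a, b)


@pytest.fixture
def rpsls5_catalog(rpsls5_system):
    a, b = rpsls5_system
    return lv.enumerate_admissible(a, b)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
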