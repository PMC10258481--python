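import numpy as np
import pytest

from abopt import DesignSpace


@pytest.fixture
def space_small() -> DesignSpace:
    """20-letter alphabet, 10-residue template, 3 designable positions."""
    return DesignSpace("toy", "ACDEFGHIKL", (2, 5, 7))


@pytest.fixture
def space4() -> DesignSpace:
    """Exhaustively enumerable toy space: 4 positions x 4 letters = 256 states."""
    return DesignSpace("toy4", "AAAA", (0, 1, 2, 3), alphabet="ACDE")


@pytest.fixture
def space_ac() -> DesignSpace:
    """Binary {A,C} alphabet, length 4, all positions designable."""
    return DesignSpace("ac", "AAAA", (0, 1, 2, 3), alphabet="AC")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
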