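import numpy as np
import pytest

from usvmuse import simulator as sim
from usvmuse.config_io import ArenaFloor, ArrayGeometry


@pytest.fixture(scope="session")
def geom() -> ArrayGeometry:
    """Study-condition array: four mics above the corners of a 66 cm arena."""
    return sim.default_geometry()


@pytest.fixture(scope="session")
def arena() -> ArenaFloor:
    return sim.default_arena()


@pytest.fixture(scope="session")
def small_arena() -> ArenaFloor:
    """A 12 cm pen: small enough for exhaustive fine-grid searches in tests."""
    return ArenaFloor(np.array([[0.25, 0.25], [0.37, 0.25],
                                [0.37, 0.37], [0.25, 0.37]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
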