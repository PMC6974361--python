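import numpy as np
import pytest

import splitdrive as sd


@pytest.fixture(scope="session")
def split_system():
    return sd.GeneticSystem("split")


@pytest.fixture(scope="session")
def linked_system():
    return sd.GeneticSystem("linked")


@pytest.fixture(scope="session")
def refractory_system():
    return sd.GeneticSystem("refractory")


@pytest.fixture(scope="session")
def default_drive():
    return sd.DriveParams()


@pytest.fixture(scope="session")
def default_cube(default_drive):
    return sd.build_cube(default_drive, "split")


@pytest.fixture(scope="session")
def small_life():
    """A small population for fast demographic tests."""
    return sd.LifeHistoryParams(n_eq=2000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
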