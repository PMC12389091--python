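import numpy as np
import pytest

from mogata import generate_fixture_library, get_task, parse_molecule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_library():
    """500 synthetic drug-like molecules, shared across the session."""
    return generate_fixture_library(500, seed=7)


@pytest.fixture(scope="session")
def pioglitazone_task():
    return get_task("pioglitazone")


@pytest.fixture
def benzene():
    return parse_molecule("c1ccccc1")


@pytest.fixture
def toluene():
    return parse_molecule("Cc1ccccc1")
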