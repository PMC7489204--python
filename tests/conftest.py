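import numpy as np
import pytest
from hypothesis import settings

from alnbench import dayhoff_frequencies, generate_test_set, get_matrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dayhoff():
    return dayhoff_frequencies()


@pytest.fixture(scope="session")
def blosum62():
    return get_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)


# Shared simulated test sets.  The 1000-pair sets match the scale of the
# published summary statistics; the 300-pair sets are the desk-scale
# surrogates used for alignment-quality checks.

@pytest.fixture(scope="session")
def ts30_1000():
    return generate_test_set(30, 1000, seed=1)


@pytest.fixture(scope="session")
def ts60_1000():
    return generate_test_set(60, 1000, seed=1)


@pytest.fixture(scope="session")
def ts120_1000():
    return generate_test_set(120, 1000, seed=1)


@pytest.fixture(scope="session")
def ts30_300():
    return generate_test_set(30, 300, seed=2)


@pytest.fixture(scope="session")
def ts120_300():
    return generate_test_set(120, 300, seed=3)
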