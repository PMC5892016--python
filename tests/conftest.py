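import numpy as np
import pytest

from spalt import canonical_spec, fixture_matrix, fixture_tree, make_protein
from spalt.align import load_score_table


@pytest.fixture(scope="session")
def blosum62():
    return load_score_table("BLOSUM62")


@pytest.fixture(scope="session")
def canonical_protein():
    """One canonical noise-free synthetic protein with planted truth."""
    return make_protein(canonical_spec(seed=42))


@pytest.fixture()
def bilateria_matrix():
    return fixture_matrix()


@pytest.fixture()
def bilateria_tree():
    return fixture_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
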