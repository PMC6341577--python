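import numpy as np
import pytest

from phyloseed.fixture import fixture_plukenetiinae, reconstruct_seed_measurements
from phyloseed.simulate import simulate_yule_tree
from phyloseed.tree import Chronogram


@pytest.fixture(scope="session")
def cherry():
    """Two-tip tree of depth 1."""
    return Chronogram.from_newick("(A:1,B:1):0;")


@pytest.fixture(scope="session")
def three_tip():
    """((A:1,B:1):1,C:2);"""
    return Chronogram.from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def yule8():
    return simulate_yule_tree(8, seed=8)


@pytest.fixture(scope="session")
def yule50():
    return simulate_yule_tree(50, seed=50, root_age=25.0)


@pytest.fixture(scope="session")
def plukfix():
    return fixture_plukenetiinae()


@pytest.fixture(scope="session")
def reconstructed_seeds():
    return reconstruct_seed_measurements()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
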