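import numpy as np
import pytest

from haplogeo import synthdata
from haplogeo.haplotypes import pairwise_steps


@pytest.fixture(scope="session")
def char_matrix():
    return synthdata.load_haplotype_matrix()


@pytest.fixture(scope="session")
def steps(char_matrix):
    return pairwise_steps(char_matrix)


@pytest.fixture(scope="session")
def pop_table():
    return synthdata.load_population_table()


@pytest.fixture(scope="session")
def rebuilt_pops():
    return synthdata.rebuild_study_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230402)
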