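import numpy as np
import pytest

from microevo.genome_io import load_fixture_tree, read_table1_fixture


@pytest.fixture(scope="session")
def tree():
    return load_fixture_tree()


@pytest.fixture(scope="session")
def table1():
    return read_table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
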