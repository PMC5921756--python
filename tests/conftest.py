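import numpy as np
import pytest

from famkit.fixtures import load_fixture, table1_records, table2_motif_list


@pytest.fixture(scope="session")
def table1():
    return table1_records()


@pytest.fixture(scope="session")
def motifs():
    return table2_motif_list()


@pytest.fixture(scope="session")
def table2_rows():
    return load_fixture("table2_motifs").payload


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
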