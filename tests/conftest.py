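import pytest

from ionmqtl import load_table3_fixture, load_table5_fixture, presence_matrix
from ionmqtl.qtl_database import GeneticMap, MarkerPosition


@pytest.fixture(scope="session")
def table3():
    return load_table3_fixture()


@pytest.fixture(scope="session")
def table5():
    return load_table5_fixture()


@pytest.fixture(scope="session")
def table3_matrix(table3):
    return presence_matrix(table3)


def make_map(population_id, markers):
    """markers: iterable of (name, linkage_group, position)."""
    return GeneticMap(
        population_id=population_id,
        markers=[MarkerPosition(n, lg, p) for n, lg, p in markers],
    )


@pytest.fixture
def simple_map():
    return make_map("p1", [("m1", "1", 0.0), ("m2", "1", 10.0), ("m3", "1", 20.0)])
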