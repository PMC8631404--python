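import pytest

from amcpipe.nomenclature import SynonymTable, build_synonym_graph
from amcpipe.synthetic import generate_proteome


@pytest.fixture
def example_graph():
    """Co-listing graph over [[A,B],[B,C],[D]]: components {A,B,C} and {D}."""
    return build_synonym_graph([["A", "B"], ["B", "C"], ["D"]])


@pytest.fixture(scope="session")
def small_proteome():
    return generate_proteome(n_genes=60, seed=3)


@pytest.fixture(scope="session")
def small_synonym_table(small_proteome):
    return SynonymTable(small_proteome.synonym_table_rows())
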