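import pytest

from gosemtk import SharedInformation, ic_table, toy1, toy2


@pytest.fixture(scope="session")
def toy1_graph_corpus():
    return toy1()


@pytest.fixture(scope="session")
def toy1_bits(toy1_graph_corpus):
    g, corpus = toy1_graph_corpus
    return g, corpus, ic_table(g, corpus, log_base=2)


@pytest.fixture(scope="session")
def toy1_si(toy1_bits):
    g, _corpus, ic = toy1_bits
    return SharedInformation(g, ic)


@pytest.fixture(scope="session")
def toy2_bits():
    g, corpus = toy2()
    return g, corpus, ic_table(g, corpus, log_base=2)


def graph_edge_pairs(g):
    """Edge set as (child, parent) pairs for oracle consumption."""
    return {(c, p) for c, p, _rel in g.edges()}
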