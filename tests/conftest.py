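import networkx as nx
import pytest

from _oracles import hub_vs_clique_chain


@pytest.fixture
def path5():
    return nx.path_graph("abcde")


@pytest.fixture
def path3():
    return nx.path_graph("abc")


@pytest.fixture
def k4():
    return nx.complete_graph(4)


@pytest.fixture
def k5():
    return nx.complete_graph(5)


@pytest.fixture
def star6():
    # center 0, five leaves 1..5
    return nx.star_graph(5)


@pytest.fixture
def two_triangles():
    # triangles {a,b,c} and {c,d,e} sharing c, plus the b-d chord
    return nx.Graph(
        [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("c", "e"), ("d", "e"), ("b", "d")]
    )


@pytest.fixture
def hub_chain():
    return hub_vs_clique_chain()
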