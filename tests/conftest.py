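import itertools

import networkx as nx
import pytest

from cipn_netgrow.knowledge_base import Interaction, KnowledgeBase, Molecule


def kb_from_edges(edges, extra_nodes=(), relation="binding", name="test-kb"):
    """Build a knowledge base from (source, target) pairs."""
    kb = KnowledgeBase(name=name)
    for u, v in edges:
        u, v = str(u), str(v)
        kb.ensure_molecule(u)
        kb.ensure_molecule(v)
        kb.add_interaction(Interaction(u, v, relation))
    for n in extra_nodes:
        kb.ensure_molecule(str(n))
    return kb


def kb_from_graph(graph, name="test-kb"):
    return kb_from_edges(graph.edges(), extra_nodes=graph.nodes(), name=name)


def brute_force_triangles(kb, gene):
    """Independent oracle: enumerate all neighbor pairs of ``gene`` and count
    the connected ones on the simple view."""
    g = kb.simple_graph
    nbrs = sorted(g.adj[gene])
    return sum(1 for u, v in itertools.combinations(nbrs, 2) if g.has_edge(u, v))


@pytest.fixture
def triangle_kb():
    return kb_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star_kb():
    return kb_from_edges([("c", l) for l in ["l1", "l2", "l3", "l4"]])


@pytest.fixture
def k4_kb():
    return kb_from_edges(itertools.combinations("ABCD", 2))
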