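import numpy as np
import pytest

import meshora as m


@pytest.fixture
def chain_store():
    """Three terms in a chain X -> Y -> Z with one annotated gene."""
    terms = [
        m.MeshTerm("X", "top", "A"),
        m.MeshTerm("Y", "middle", "A"),
        m.MeshTerm("Z", "leaf", "A", qualifiers={"metabolism"}, synonyms={"leafish"}),
    ]
    links = [m.GeneMeshLink(101, "Z", "gene2pubmed", {70001})]
    return m.create_store(terms, [("X", "Y"), ("Y", "Z")], links, {"organism": "toy"})


@pytest.fixture
def diamond_store():
    """Multi-parent DAG: P1 -> C <- P2, both parents under R."""
    terms = [m.MeshTerm(t, t.lower(), "B") for t in ("R", "P1", "P2", "C")]
    edges = [("R", "P1"), ("R", "P2"), ("P1", "C"), ("P2", "C")]
    return m.create_store(terms, edges, [])


def random_dag(rng, n_nodes):
    """Random DAG over term ids, edges only from lower to higher index."""
    terms = [m.MeshTerm(f"N{i:03d}", f"node {i}", "C") for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        for _ in range(int(rng.integers(1, 4))):
            j = int(rng.integers(i))
            edges.append((f"N{j:03d}", f"N{i:03d}"))
    return terms, sorted(set(edges))


def bfs_reachability(n_nodes, edges):
    """Independent reachability oracle: plain breadth-first search on an
    adjacency list, no graph library."""
    adj = {}
    for parent, child in edges:
        adj.setdefault(parent, set()).add(child)
    reach = {}
    for start in [f"N{i:03d}" for i in range(n_nodes)]:
        seen, frontier = set(), [start]
        while frontier:
            node = frontier.pop()
            for nxt in adj.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        reach[start] = seen
    return reach


@pytest.fixture
def rng():
    return np.random.default_rng(20140401)
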