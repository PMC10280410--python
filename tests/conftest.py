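"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's cached/incremental code
paths: community state is recomputed from raw adjacency every time, so they
can arbitrate whether the fast paths are correct.
"""

from __future__ import annotations

import random

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from foxcd import Cover, Graph

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def graph_from_edges(edges, labels=None) -> Graph:
    return Graph.from_edges(edges, labels=labels)


def random_graph(n: int, avg_degree: float, seed: int) -> Graph:
    """Erdos-Renyi graph via networkx (oracle-side generator), all n nodes kept."""
    p = min(1.0, avg_degree / max(n - 1, 1))
    g = nx.gnp_random_graph(n, p, seed=seed)
    labels = [str(i) for i in range(n)]
    return Graph.from_edges(
        ((str(u), str(v)) for u, v in g.edges()), labels=labels
    )


def random_cover(graph: Graph, n_communities: int, seed: int) -> Cover:
    """Random overlapping cover: each community a random node subset (>=2)."""
    rng = random.Random(seed)
    nodes = list(range(graph.n_nodes))
    member_sets = []
    for _ in range(n_communities):
        size = rng.randint(2, max(2, graph.n_nodes // 2))
        member_sets.append(set(rng.sample(nodes, min(size, len(nodes)))))
    return Cover.from_communities(graph, member_sets)


# --------------------------------------------------------------- oracles

def naive_wcc_hat_total(cover: Cover, cc_global: float) -> float:
    """Cover score recomputed from raw adjacency only (no caches).

    Independent arbiter for the cached/incremental implementation: density,
    in-community degrees and the per-node terms are all derived afresh from
    the graph's adjacency sets.
    """
    graph = cover.graph
    total = 0.0
    for cid in cover.communities:
        members = cover.communities[cid]
        size = len(members)
        if size <= 1:
            continue
        internal = (
            sum(len(graph.adjacency[x] & members) for x in members) // 2
        )
        p = internal / (size * (size - 1) / 2)
        for x in members:
            d_total = graph.degree(x)
            d_in = len(graph.adjacency[x] & members)
            if d_total <= 1 or cc_global == 0.0 or d_in <= 1 or p == 0.0:
                continue
            et_c = d_in * (d_in - 1) / 2 * p
            et_v = d_total * (d_total - 1) / 2 * cc_global
            total += (et_c / et_v) * d_total / ((size - 1) + (d_total - d_in))
    return total


def brute_force_triangles(graph: Graph, node: int) -> int:
    """Triangle count by exhaustive neighbor-pair enumeration."""
    neigh = sorted(graph.adjacency[node])
    return sum(
        1
        for i, u in enumerate(neigh)
        for v in neigh[i + 1 :]
        if v in graph.adjacency[u]
    )


# --------------------------------------------------------------- fixtures

@pytest.fixture
def triangle() -> Graph:
    """K3 on labels a, b, c."""
    return graph_from_edges([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture
def two_triangles() -> Graph:
    """Two disjoint triangles: a-b-c and d-e-f."""
    return graph_from_edges(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f")]
    )


@pytest.fixture
def kite() -> Graph:
    """The 4-node worked example: edges ab, ac, bc, ad, bd (cc = 5/6)."""
    return graph_from_edges([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "d")])


@pytest.fixture
def five_path() -> Graph:
    """Path a-b-c-d-e."""
    return graph_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


def node(graph: Graph, label: str) -> int:
    return graph.label_index[label]
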