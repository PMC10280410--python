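"""Per-node triangle statistics, processing order, and the initial cover.

Node processing order: decreasing local clustering coefficient, ties broken
by decreasing degree, remaining ties by ascending dense node index. More
"central" nodes (whose neighborhoods are closer to cliques) are processed
first so that peripheral nodes adapt to their decisions.

The initial cover is a greedy non-overlapping decomposition: traversing the
order, an unassigned node opens a new community and pulls in all of its
still-unassigned neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_io import Graph

__all__ = [
    "NodeStats",
    "triangle_count",
    "local_cc",
    "global_cc",
    "compute_stats",
    "node_order",
    "initial_cover",
]


@dataclass(frozen=True)
class NodeStats:
    """Triangle counts k_i, degrees d_i, local CC(i), and their mean cc."""

    k: tuple[int, ...]
    d: tuple[int, ...]
    cc_local: tuple[float, ...]
    cc_global: float


def triangle_count(graph: Graph, node: int) -> int:
    """Number of edges between neighbors of ``node`` (= triangles through it)."""
    adj = graph.adjacency
    neigh = adj[node]
    count = 0
    for u in neigh:
        # iterate the smaller set of the pair; count each pair once via <
        au = adj[u]
        if len(au) < len(neigh):
            count += sum(1 for v in au if v > u and v in neigh)
        else:
            count += sum(1 for v in neigh if v > u and v in au)
    return count


def local_cc(graph: Graph, node: int) -> float:
    """Local clustering coefficient: k_i / C(d_i, 2), and 0 when d_i <= 1."""
    d = graph.degree(node)
    if d <= 1:
        return 0.0
    return triangle_count(graph, node) / (d * (d - 1) / 2)


def global_cc(graph: Graph) -> float:
    """Arithmetic mean of the local clustering coefficient over ALL nodes.

    Degree-<=1 nodes count as 0. Note this is the mean-of-local-CC statistic,
    not transitivity (the global triangle/triplet ratio); the two differ on
    most graphs.
    """
    if graph.n_nodes == 0:
        return 0.0
    return sum(local_cc(graph, i) for i in range(graph.n_nodes)) / graph.n_nodes


def compute_stats(graph: Graph) -> NodeStats:
    k = tuple(triangle_count(graph, i) for i in range(graph.n_nodes))
    d = tuple(graph.degrees)
    cc = tuple(
        (2 * k[i] / (d[i] * (d[i] - 1))) if d[i] > 1 else 0.0
        for i in range(graph.n_nodes)
    )
    cc_global = sum(cc) / len(cc) if cc else 0.0
    return NodeStats(k=k, d=d, cc_local=cc, cc_global=cc_global)


def node_order(graph: Graph, stats: NodeStats) -> list[int]:
    """Deterministic processing order.

    Sort key: cc_local descending, degree descending, dense index ascending.
    Returns a permutation of 0..n-1.
    """
    return sorted(
        range(graph.n_nodes),
        key=lambda i: (-stats.cc_local[i], -stats.d[i], i),
    )


def initial_cover(graph: Graph, order: list[int]):
    """Greedy non-overlapping starting cover.

    Every node ends in exactly one community; isolated nodes (or nodes whose
    neighbors were all claimed earlier) form singletons, which the optimizer
    prunes after its first iteration.
    """
    from .wcc import Cover

    assigned = [False] * graph.n_nodes
    member_sets: list[set[int]] = []
    for x in order:
        if assigned[x]:
            continue
        community = {x}
        assigned[x] = True
        for y in graph.adjacency[x]:
            if not assigned[y]:
                community.add(y)
                assigned[y] = True
        member_sets.append(community)
    return Cover.from_communities(graph, member_sets)
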