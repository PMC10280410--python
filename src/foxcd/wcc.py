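"""The weighted community clustering (WCC) metric and its mean-field estimate.

Exact WCC rates how well a node x fits a community C by the fraction of x's
triangles closed inside C, damped by how much of x's triangle neighborhood
lies outside C:

    WCC(x, C) = t(x,C)/t(x,V) * vt(x,V) / (|C \\ {x}| + vt(x, V \\ C))

with t(x,S) the number of triangles through x with both co-vertices in S and
vt(x,S) the number of nodes in S sharing at least one triangle with x; the
score is 0 when x forms no triangles at all. Community and cover scores are
the sums over members and communities respectively.

Counting triangles per candidate move is expensive, so the optimizer uses a
mean-field estimate (WCC-hat): assuming edges inside C are homogeneously
distributed with density p, the expected in-community triangle count is
E[t(x,C)] = C(deg(x,C), 2) * p, and globally E[t(x,V)] = C(deg(x,V), 2) * cc
with cc the mean local clustering coefficient; the vt terms are replaced by
their degree upper bounds:

    WCC-hat(x, C) = E[t(x,C)]/E[t(x,V)] * deg(x,V) / (|C \\ {x}| + deg(x, V\\C))

and 0 when E[t(x,V)] = 0. Both members and join candidates are scored with
the same formula; for a non-member, |C \\ {x}| = |C|.

The :class:`Cover` container caches per-community internal edge counts and
per-member in-community degrees so that evaluating and applying single-node
join/leave moves touches only the affected community: the WCC-hat term of any
node y in any other community C' does not depend on x's membership in C.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_io import Graph

__all__ = [
    "Cover",
    "MetricContext",
    "community_density",
    "wcc_hat_node",
    "wcc_hat_community",
    "wcc_hat_total",
    "wcc_exact_node",
    "wcc_exact_total",
    "delta_join",
    "delta_leave",
]


@dataclass(frozen=True)
class MetricContext:
    """Graph-level constants frozen at preprocessing time.

    ``cc_global`` (mean local clustering coefficient) and the degree table
    stay constant for the whole optimization run; only community state moves.
    """

    cc_global: float
    degrees: tuple[int, ...]


class Cover:
    """A mutable overlapping community assignment with incremental caches.

    State:
      communities:     community-ID -> set of member node indices
      memberships:     node index -> set of community IDs
      internal_edges:  community-ID -> number of edges with both ends inside
      in_degree:       community-ID -> {member -> deg(member, community)}

    Community IDs are never reused within a run (monotone ``next_id``).
    """

    __slots__ = ("graph", "communities", "memberships", "internal_edges", "in_degree", "next_id")

    def __init__(self, graph: Graph):
        self.graph = graph
        self.communities: dict[int, set[int]] = {}
        self.memberships: dict[int, set[int]] = {i: set() for i in range(graph.n_nodes)}
        self.internal_edges: dict[int, int] = {}
        self.in_degree: dict[int, dict[int, int]] = {}
        self.next_id = 0

    @classmethod
    def from_communities(cls, graph: Graph, member_sets) -> "Cover":
        cover = cls(graph)
        for members in member_sets:
            cover.add_community(members)
        return cover

    # ------------------------------------------------------------------ state

    def add_community(self, members) -> int:
        cid = self.next_id
        self.next_id += 1
        members = set(members)
        self.communities[cid] = members
        indeg: dict[int, int] = {}
        internal = 0
        adj = self.graph.adjacency
        for x in members:
            dx = len(adj[x] & members)
            indeg[x] = dx
            internal += dx
            self.memberships[x].add(cid)
        self.internal_edges[cid] = internal // 2
        self.in_degree[cid] = indeg
        return cid

    def add_member(self, x: int, cid: int) -> None:
        members = self.communities[cid]
        if x in members:
            raise ValueError(f"node {x} is already a member of community {cid}")
        adj_x = self.graph.adjacency[x]
        indeg = self.in_degree[cid]
        dx = 0
        for y in members:
            if y in adj_x:
                indeg[y] += 1
                dx += 1
        members.add(x)
        indeg[x] = dx
        self.internal_edges[cid] += dx
        self.memberships[x].add(cid)

    def remove_member(self, x: int, cid: int) -> None:
        members = self.communities[cid]
        if x not in members:
            raise ValueError(f"node {x} is not a member of community {cid}")
        adj_x = self.graph.adjacency[x]
        indeg = self.in_degree[cid]
        members.discard(x)
        dx = indeg.pop(x)
        for y in members:
            if y in adj_x:
                indeg[y] -= 1
        self.internal_edges[cid] -= dx
        self.memberships[x].discard(cid)

    def remove_community(self, cid: int) -> None:
        for x in self.communities.pop(cid):
            self.memberships[x].discard(cid)
        del self.internal_edges[cid]
        del self.in_degree[cid]

    def copy(self) -> "Cover":
        dup = Cover(self.graph)
        dup.communities = {c: set(m) for c, m in self.communities.items()}
        dup.memberships = {x: set(s) for x, s in self.memberships.items()}
        dup.internal_edges = dict(self.internal_edges)
        dup.in_degree = {c: dict(d) for c, d in self.in_degree.items()}
        dup.next_id = self.next_id
        return dup

    def member_sets(self) -> list[frozenset[int]]:
        """Member sets in ascending community-ID order (canonical form)."""
        return [frozenset(self.communities[c]) for c in sorted(self.communities)]

    def rebuild_caches(self) -> tuple[dict[int, int], dict[int, dict[int, int]]]:
        """Recompute internal_edges and in_degree from scratch (verification)."""
        internal: dict[int, int] = {}
        indeg: dict[int, dict[int, int]] = {}
        adj = self.graph.adjacency
        for cid, members in self.communities.items():
            d = {x: len(adj[x] & members) for x in members}
            indeg[cid] = d
            internal[cid] = sum(d.values()) // 2
        return internal, indeg

    def __len__(self) -> int:
        return len(self.communities)


# -------------------------------------------------------------- mean-field

def community_density(cover: Cover, cid: int) -> float:
    """Edge density p = internal_edges / C(|C|, 2); 0 for |C| <= 1."""
    size = len(cover.communities[cid])
    if size <= 1:
        return 0.0
    return cover.internal_edges[cid] / (size * (size - 1) / 2)


def _hat_term(deg_in: int, deg_total: int, size_excl_x: int, p: float, cc: float) -> float:
    """One Eq.-style WCC-hat term from scalar ingredients.

    deg_in = deg(x,C); deg_total = deg(x,V); size_excl_x = |C \\ {x}|.
    """
    if deg_total <= 1 or cc == 0.0:
        return 0.0  # E[t(x,V)] = 0 branch
    if deg_in <= 1 or p == 0.0:
        return 0.0  # binomial term vanishes
    et_c = deg_in * (deg_in - 1) / 2 * p
    et_v = deg_total * (deg_total - 1) / 2 * cc
    boundary = deg_total - deg_in  # deg(x, V \ C) for simple graphs
    return (et_c / et_v) * deg_total / (size_excl_x + boundary)


def wcc_hat_node(x: int, cid: int, cover: Cover, ctx: MetricContext) -> float:
    """Mean-field fit of node x to community cid (member or join candidate)."""
    members = cover.communities[cid]
    is_member = x in members
    deg_in = (
        cover.in_degree[cid][x]
        if is_member
        else len(cover.graph.adjacency[x] & members)
    )
    size_excl = len(members) - 1 if is_member else len(members)
    return _hat_term(
        deg_in, ctx.degrees[x], size_excl, community_density(cover, cid), ctx.cc_global
    )


def _community_hat(
    members_sorted, indeg: dict[int, int], internal: int, size: int, ctx: MetricContext
) -> float:
    """WCC-hat of a (possibly hypothetical) community from its caches.

    Accumulation runs in ascending member index so sums are bit-reproducible.
    """
    if size <= 1:
        return 0.0
    p = internal / (size * (size - 1) / 2)
    total = 0.0
    for x in members_sorted:
        total += _hat_term(indeg[x], ctx.degrees[x], size - 1, p, ctx.cc_global)
    return total


def wcc_hat_community(cid: int, cover: Cover, ctx: MetricContext) -> float:
    """Sum of members' WCC-hat terms for one community."""
    members = cover.communities[cid]
    return _community_hat(
        sorted(members),
        cover.in_degree[cid],
        cover.internal_edges[cid],
        len(members),
        ctx,
    )


def wcc_hat_total(cover: Cover, ctx: MetricContext) -> float:
    """Cover-level WCC-hat: sum over communities (ascending ID order)."""
    return sum(wcc_hat_community(c, cover, ctx) for c in sorted(cover.communities))


# ------------------------------------------------------------- move deltas

def delta_join(x: int, cid: int, cover: Cover, ctx: MetricContext) -> float:
    """Change in cover WCC-hat if x joined community cid. No mutation.

    Only cid's terms change (no other community's term depends on x's
    membership in cid), so the delta is evaluated community-locally against
    a hypothetical cache with x added.
    """
    members = cover.communities[cid]
    if x in members:
        raise ValueError(f"delta_join: node {x} already in community {cid}")
    before = wcc_hat_community(cid, cover, ctx)

    adj_x = cover.graph.adjacency[x]
    indeg = cover.in_degree[cid]
    deg_x_in = 0
    hypo = {}
    for y in members:
        if y in adj_x:
            hypo[y] = indeg[y] + 1
            deg_x_in += 1
        else:
            hypo[y] = indeg[y]
    hypo[x] = deg_x_in
    after = _community_hat(
        sorted(hypo),
        hypo,
        cover.internal_edges[cid] + deg_x_in,
        len(members) + 1,
        ctx,
    )
    return after - before


def delta_leave(x: int, cid: int, cover: Cover, ctx: MetricContext) -> float:
    """Change in cover WCC-hat if x left community cid. No mutation."""
    members = cover.communities[cid]
    if x not in members:
        raise ValueError(f"delta_leave: node {x} not in community {cid}")
    before = wcc_hat_community(cid, cover, ctx)

    adj_x = cover.graph.adjacency[x]
    indeg = cover.in_degree[cid]
    hypo = {}
    for y in members:
        if y == x:
            continue
        hypo[y] = indeg[y] - 1 if y in adj_x else indeg[y]
    after = _community_hat(
        sorted(hypo),
        hypo,
        cover.internal_edges[cid] - indeg[x],
        len(members) - 1,
        ctx,
    )
    return after - before


# ------------------------------------------------------------ exact oracle

def _triangle_covertices(x: int, graph: Graph) -> dict[int, int]:
    """For each neighbor u of x, the number of triangles x-u-v (v any node)."""
    adj = graph.adjacency
    neigh = adj[x]
    return {u: len(adj[u] & neigh) for u in neigh}


def wcc_exact_node(x: int, cid: int, cover: Cover, graph: Graph) -> float:
    """Exact WCC(x, C) by explicit triangle enumeration (slow oracle)."""
    members = cover.communities[cid]
    adj = graph.adjacency
    neigh = adj[x]

    tri_with = _triangle_covertices(x, graph)
    t_total = sum(tri_with.values()) // 2
    if t_total == 0:
        return 0.0
    # triangles with both co-vertices in C
    in_c = [u for u in neigh if u in members]
    t_in = 0
    for i, u in enumerate(in_c):
        au = adj[u]
        for v in in_c[i + 1:]:
            if v in au:
                t_in += 1
    vt_total = sum(1 for u in neigh if tri_with[u] > 0)
    vt_outside = sum(1 for u in neigh if tri_with[u] > 0 and u not in members)
    size_excl = len(members) - 1 if x in members else len(members)
    return (t_in / t_total) * vt_total / (size_excl + vt_outside)


def wcc_exact_total(cover: Cover, graph: Graph) -> float:
    """Exact cover-level WCC (double sum of the per-node oracle)."""
    return sum(
        wcc_exact_node(x, cid, cover, graph)
        for cid in sorted(cover.communities)
        for x in sorted(cover.communities[cid])
    )
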