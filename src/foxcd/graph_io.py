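"""Reading and writing graphs and community covers.

The on-disk graph format is the SNAP edge-list dialect: one edge per line as
two whitespace-separated node labels, with ``#``-prefixed comment lines.
Input graphs are normalised to simple undirected graphs: duplicate and
reversed edges are collapsed, self-loops dropped, and node labels re-indexed
to the dense range ``0..n-1`` in order of first appearance.

Covers (overlapping community assignments) are written one community per
line, members as original labels separated by single spaces — the convention
of the published SNAP ground-truth community files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

__all__ = ["Graph", "GraphParseError", "read_edge_list", "write_cover", "read_cover"]


class GraphParseError(ValueError):
    """Raised for malformed edge-list or cover files."""


@dataclass(frozen=True)
class Graph:
    """An immutable simple undirected graph with dense node indices.

    Attributes
    ----------
    n_nodes:
        Number of nodes; valid indices are exactly ``0..n_nodes-1``.
    adjacency:
        Per-node frozenset of neighbor indices. Symmetric, no self-loops.
    labels:
        Dense index -> original input label (opaque string).
    dropped_self_loops, dropped_duplicates:
        Preprocessing counters, for logging/manifests.
    """

    n_nodes: int
    adjacency: tuple[frozenset[int], ...]
    labels: tuple[str, ...]
    dropped_self_loops: int = 0
    dropped_duplicates: int = 0
    label_index: dict[str, int] = field(compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_index:
            object.__setattr__(
                self, "label_index", {lab: i for i, lab in enumerate(self.labels)}
            )

    def degree(self, node: int) -> int:
        return len(self.adjacency[node])

    @property
    def degrees(self) -> list[int]:
        return [len(a) for a in self.adjacency]

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def edges(self) -> Iterable[tuple[int, int]]:
        for u in range(self.n_nodes):
            for v in self.adjacency[u]:
                if u < v:
                    yield u, v

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        *,
        labels: Sequence[str] | None = None,
    ) -> "Graph":
        """Build a simple graph from an iterable of label pairs.

        Labels are densely re-indexed by first appearance. Self-loops are
        dropped (counted), duplicate/reversed edges collapsed (counted).
        If ``labels`` is given, it pre-seeds the index order and may include
        isolated nodes.
        """
        index: dict[str, int] = {}
        adj: list[set[int]] = []
        if labels is not None:
            for lab in labels:
                lab = str(lab)
                if lab not in index:
                    index[lab] = len(adj)
                    adj.append(set())

        def node_id(lab: str) -> int:
            i = index.get(lab)
            if i is None:
                i = len(adj)
                index[lab] = i
                adj.append(set())
            return i

        loops = 0
        dups = 0
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                loops += 1
                # register the node even if its only line is a self-loop
                node_id(a)
                continue
            u, v = node_id(a), node_id(b)
            if v in adj[u]:
                dups += 1
                continue
            adj[u].add(v)
            adj[v].add(u)

        ordered = sorted(index, key=index.get)
        return cls(
            n_nodes=len(adj),
            adjacency=tuple(frozenset(s) for s in adj),
            labels=tuple(ordered),
            dropped_self_loops=loops,
            dropped_duplicates=dups,
        )


def read_edge_list(path) -> Graph:
    """Parse a SNAP-dialect edge list into a :class:`Graph`.

    Each non-comment line must contain exactly two whitespace-separated
    tokens; extra tokens are a hard error (they usually indicate a weighted
    edge list, which is out of scope). Raises :class:`GraphParseError` with
    the offending line number, and on an edgeless result.
    """
    edges: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise GraphParseError(
                    f"{path}: line {lineno}: expected 2 tokens, got {len(tokens)}"
                )
            edges.append((tokens[0], tokens[1]))
    if not edges:
        raise GraphParseError(f"{path}: no edges found")
    graph = Graph.from_edges(edges)
    if graph.dropped_self_loops or graph.dropped_duplicates:
        log.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path,
            graph.dropped_self_loops,
            graph.dropped_duplicates,
        )
    if graph.n_edges == 0:
        raise GraphParseError(f"{path}: no edges remain after preprocessing")
    return graph


def write_cover(cover, graph: Graph, path) -> None:
    """Write a cover: one community per line, original labels, sorted.

    Communities appear in ascending community-ID order, members in ascending
    original-label order (lexicographic on the opaque label strings), so the
    output is canonical and byte-reproducible.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for cid in sorted(cover.communities):
            members = sorted(graph.labels[x] for x in cover.communities[cid])
            fh.write(" ".join(members) + "\n")


def read_cover(path, graph: Graph):
    """Read a cover file (one community per line) against ``graph``.

    Unknown labels raise :class:`GraphParseError` naming label and line.
    Duplicate lines yield distinct community IDs (duplicates are legal before
    post-processing).
    """
    from .wcc import Cover  # local import to avoid a cycle

    member_sets: list[set[int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            members = set()
            for tok in stripped.split():
                idx = graph.label_index.get(tok)
                if idx is None:
                    raise GraphParseError(
                        f"{path}: line {lineno}: unknown node label {tok!r}"
                    )
                members.add(idx)
            member_sets.append(members)
    return Cover.from_communities(graph, member_sets)
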