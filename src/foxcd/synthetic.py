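"""Seeded generator of graphs with planted overlapping communities.

Emulates "by bond" community structure: blocks of nodes densely wired
internally (probability ``p_in``, producing many closed triangles) over a
sparse background (``p_out``), with a controllable fraction of nodes that
belong to two adjacent communities — the planted overlap. The planted cover
serves as ground truth for recovery experiments; a single integer seed makes
every draw reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph_io import Graph
from .wcc import Cover

__all__ = ["PlantedSpec", "generate"]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted-cover benchmark graph.

    n_communities:   number of planted communities.
    community_size:  primary members per community (int, or one size each).
    shared_fraction: fraction of nodes also joining the next community
                     (adjacent index, wrapping), planting per-node overlap.
    p_in:            edge probability inside a community.
    p_out:           edge probability for all remaining node pairs.
    seed:            integer seed for all randomness.
    """

    n_communities: int
    community_size: int | Sequence[int]
    shared_fraction: float = 0.0
    p_in: float = 0.9
    p_out: float = 0.01
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.community_size, int):
            return [self.community_size] * self.n_communities
        return list(self.community_size)

    def validate(self) -> None:
        sizes = self.sizes()
        if self.n_communities < 1 or len(sizes) != self.n_communities:
            raise ValueError("need n_communities >= 1 matching the size list")
        if any(s < 2 for s in sizes):
            raise ValueError("every planted community needs >= 2 members")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not (0.0 <= self.shared_fraction < 1.0):
            raise ValueError("need 0 <= shared_fraction < 1")
        if sum(sizes) < 3:
            raise ValueError("graph must have at least 3 nodes")


def generate(spec: PlantedSpec) -> tuple[Graph, Cover]:
    """Draw one planted-cover graph; identical spec (incl. seed) => identical output.

    Each node gets one primary community; a ``shared_fraction`` slice of each
    community (its lowest-index members, deterministic) additionally joins
    the next community. Intra-community pairs are kept with ``p_in``, all
    other pairs with ``p_out``. Node labels are the decimal indices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes()
    n = sum(sizes)

    communities: list[set[int]] = []
    start = 0
    for s in sizes:
        communities.append(set(range(start, start + s)))
        start += s
    if spec.shared_fraction > 0.0 and spec.n_communities > 1:
        for k, s in enumerate(sizes):
            n_shared = int(round(spec.shared_fraction * s))
            base = sum(sizes[:k])
            nxt = communities[(k + 1) % spec.n_communities]
            for x in range(base, base + n_shared):
                nxt.add(x)

    # mark intra-community pairs, then one Bernoulli sweep over all pairs
    intra = np.zeros((n, n), dtype=bool)
    for members in communities:
        idx = np.fromiter(sorted(members), dtype=np.intp)
        intra[np.ix_(idx, idx)] = True
    iu, ju = np.triu_indices(n, k=1)
    probs = np.where(intra[iu, ju], spec.p_in, spec.p_out)
    keep = rng.random(len(probs)) < probs

    labels = [str(i) for i in range(n)]
    edges = [(labels[a], labels[b]) for a, b in zip(iu[keep], ju[keep])]
    graph = Graph.from_edges(edges, labels=labels)
    cover = Cover.from_communities(graph, communities)
    return graph, cover
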