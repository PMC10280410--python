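"""Cover quality metrics: cover F1 against a ground truth, and summary stats.

Cover F1 is the standard asymmetric score for overlapping community
detection: each detected community C' is matched to the ground-truth
community C maximizing the harmonic mean of precision |C∩C'|/|C'| and recall
|C∩C'|/|C|, and the per-community maxima are averaged over the detected
cover. Disjoint pairs contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_io import Graph
from .wcc import Cover

__all__ = ["CoverStats", "cover_f1", "community_f1", "cover_stats"]


@dataclass(frozen=True)
class CoverStats:
    """Community count, size extremes, and per-node membership overlap.

    ``mean_memberships`` averages over nodes with at least one community (the
    reported convention); ``mean_memberships_all_nodes`` divides by the full
    node count instead. Memberless nodes are counted separately.
    """

    community_count: int
    size_min: int
    size_mean: float
    size_max: int
    mean_memberships: float
    mean_memberships_all_nodes: float
    memberless_count: int


def community_f1(detected: frozenset | set, truth: frozenset | set) -> float:
    """F1 of one detected community against one truth community."""
    overlap = len(detected & truth)
    if overlap == 0:
        return 0.0
    precision = overlap / len(detected)
    recall = overlap / len(truth)
    return 2 * precision * recall / (precision + recall)


def cover_f1(detected: Cover, truth: Cover) -> float:
    """Mean best-match F1 of detected communities vs. the truth cover.

    Asymmetric: averages over *detected* communities. Raises on an empty
    detected cover (the mean is undefined).
    """
    det_sets = detected.member_sets()
    truth_sets = truth.member_sets()
    if not det_sets:
        raise ValueError("cover_f1: detected cover has no communities")
    if not truth_sets:
        raise ValueError("cover_f1: truth cover has no communities")
    total = 0.0
    for c_det in det_sets:
        total += max(community_f1(c_det, c_true) for c_true in truth_sets)
    return total / len(det_sets)


def cover_stats(cover: Cover, graph: Graph) -> CoverStats:
    """Structural summary of a cover: counts, sizes, membership overlap."""
    sizes = [len(m) for m in cover.communities.values()]
    if not sizes:
        raise ValueError("cover_stats: empty cover")
    total_memberships = sum(sizes)
    assigned = sum(1 for x in range(graph.n_nodes) if cover.memberships[x])
    memberless = graph.n_nodes - assigned
    return CoverStats(
        community_count=len(sizes),
        size_min=min(sizes),
        size_mean=total_memberships / len(sizes),
        size_max=max(sizes),
        mean_memberships=total_memberships / assigned if assigned else 0.0,
        mean_memberships_all_nodes=total_memberships / graph.n_nodes,
        memberless_count=memberless,
    )
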