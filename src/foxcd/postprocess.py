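"""Optional cover cleanup: duplicate and nested community removal.

Overlapping optimization can leave communities with identical member sets or
communities fully contained in larger ones. Whether that is noise or signal
depends on the domain (nested communities do occur in real ground truths,
e.g. subgroups inside departments), so cleanup is opt-in and disabled by
default.
"""

from __future__ import annotations

from .wcc import Cover

__all__ = ["dedupe", "remove_nested", "postprocess"]


def _rebuild(cover: Cover, keep_ids: list[int]) -> Cover:
    """New Cover holding only ``keep_ids``, preserving IDs and caches."""
    out = Cover(cover.graph)
    out.next_id = cover.next_id
    for cid in sorted(keep_ids):
        out.communities[cid] = set(cover.communities[cid])
        out.internal_edges[cid] = cover.internal_edges[cid]
        out.in_degree[cid] = dict(cover.in_degree[cid])
        for x in cover.communities[cid]:
            out.memberships[x].add(cid)
    return out


def dedupe(cover: Cover) -> Cover:
    """Drop communities with identical member sets, keeping the lowest ID."""
    seen: dict[frozenset[int], int] = {}
    for cid in sorted(cover.communities):
        key = frozenset(cover.communities[cid])
        seen.setdefault(key, cid)
    return _rebuild(cover, list(seen.values()))


def remove_nested(cover: Cover) -> Cover:
    """Drop every community strictly contained in another surviving one.

    Supersets are kept (coverage never shrinks below the largest containers).
    Applied after :func:`dedupe` the result has no subset pairs at all.
    Containment is tested via per-node community indexes over size-sorted
    candidates, not all pairs.
    """
    # node -> IDs of communities containing it, for candidate lookup
    by_node: dict[int, set[int]] = {}
    for cid, members in cover.communities.items():
        for x in members:
            by_node.setdefault(x, set()).add(cid)

    sizes = {cid: len(m) for cid, m in cover.communities.items()}
    keep: list[int] = []
    for cid in sorted(cover.communities):
        members = cover.communities[cid]
        # candidate supersets: communities containing some member, larger size
        pivot = min(members, key=lambda x: len(by_node[x]))
        candidates = [
            other
            for other in by_node[pivot]
            if other != cid and sizes[other] > sizes[cid]
        ]
        if not any(members <= cover.communities[other] for other in candidates):
            keep.append(cid)
    return _rebuild(cover, keep)


def postprocess(cover: Cover) -> Cover:
    """Dedupe, then remove nested communities."""
    return remove_nested(dedupe(cover))
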