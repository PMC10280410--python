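"""Greedy WCC-hat optimization with batched (parallelizable) node updates.

Each node, visited in the fixed preprocessing order, gets at most one
*join*-action (into the neighboring community raising the cover score most)
and one *leave*-action (from the own community whose departure raises it
most). In the sequential variant actions are applied immediately per node;
in the batched variant the best actions for a queue of ``queue_size`` nodes
are computed against one frozen cover snapshot and then bulk-applied in node
order (leave before join per node). Batch members therefore do not see each
other's moves until the next block — the trade that makes the per-node
searches embarrassingly parallel.

After every iteration, communities that degenerated to fewer than two
members are removed: a single-member community contributes nothing to the
score and can never be improved by a join (the in-community degree of any
candidate is at most 1, so the expected triangle count vanishes). Removing a
node's last community does not remove the node; memberless nodes may re-join
later.

The run stops when the absolute relative change of the cover score between
consecutive iterations falls below ``wcc_threshold`` (default 0.01). The
whole procedure is deterministic: no randomness enters anywhere, and the
result is invariant to ``worker_count`` by construction (actions are a pure
function of the frozen snapshot; apply order is fixed).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .graph_io import Graph
from .preprocess import compute_stats, initial_cover, node_order
from .wcc import (
    Cover,
    MetricContext,
    delta_join,
    delta_leave,
    wcc_hat_community,
    wcc_hat_total,
)

__all__ = [
    "ChangeAction",
    "RunConfig",
    "IterationRecord",
    "RunTrace",
    "best_actions",
    "apply_actions",
    "run_iteration",
    "run",
    "run_sequential_reference",
]


@dataclass(frozen=True)
class ChangeAction:
    """One node's best join and leave targets against a frozen snapshot.

    Targets are ``None`` when no candidate yields a strictly positive score
    delta. Ties between equal maximal deltas go to the lowest community ID.
    """

    node: int
    join_target: int | None = None
    join_delta: float = 0.0
    leave_target: int | None = None
    leave_delta: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    """Hyper-parameters of a detection run.

    queue_size:    nodes per frozen-snapshot batch (1 = strictly sequential).
    worker_count:  threads used to evaluate a batch; never affects results.
    wcc_threshold: stop when |relative score change| drops below this.
    """

    queue_size: int = 1
    worker_count: int = 1
    wcc_threshold: float = 0.01
    max_iterations: int | None = None
    dump_iterations: bool = False

    def __post_init__(self) -> None:
        if self.queue_size < 1:
            raise ValueError("queue_size must be >= 1")
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")
        if not (0.0 < self.wcc_threshold < 1.0):
            raise ValueError("wcc_threshold must be in (0, 1)")


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    wcc_hat: float
    relative_change: float
    joins_applied: int
    leaves_applied: int
    actions_skipped: int
    communities_removed: int
    community_count: int


@dataclass
class RunTrace:
    """Per-iteration convergence record of one run."""

    initial_wcc_hat: float = 0.0
    records: list[IterationRecord] = field(default_factory=list)

    @property
    def iterations(self) -> int:
        return len(self.records)

    def wcc_values(self) -> list[float]:
        return [r.wcc_hat for r in self.records]

    def to_dict(self) -> dict:
        return {
            "initial_wcc_hat": self.initial_wcc_hat,
            "iterations": self.iterations,
            "records": [vars(r) for r in self.records],
        }


def best_actions(x: int, cover: Cover, ctx: MetricContext) -> ChangeAction:
    """Best join and leave for node x against the (unmutated) cover.

    Join candidates: communities of x's neighbors that x is not in.
    Leave candidates: x's own communities. Only strictly positive deltas
    produce a target; equal deltas resolve to the lowest community ID
    (candidates are scanned in ascending ID order with a strict > update).
    """
    own = cover.memberships[x]
    neighbor_comms: set[int] = set()
    for y in cover.graph.adjacency[x]:
        neighbor_comms |= cover.memberships[y]
    join_candidates = sorted(neighbor_comms - own)

    join_target = None
    join_best = 0.0
    for cid in join_candidates:
        d = delta_join(x, cid, cover, ctx)
        if d > 0.0 and d > join_best:
            join_target, join_best = cid, d

    leave_target = None
    leave_best = 0.0
    for cid in sorted(own):
        d = delta_leave(x, cid, cover, ctx)
        if d > 0.0 and d > leave_best:
            leave_target, leave_best = cid, d

    return ChangeAction(x, join_target, join_best, leave_target, leave_best)


def apply_actions(
    actions: list[ChangeAction], cover: Cover, ctx: MetricContext
) -> tuple[int, int, int, float]:
    """Apply a batch of actions in node-order sequence; leave before join.

    Actions were decided against a snapshot, so by apply time a precondition
    may have lapsed (defensive: the node already left, or already joined);
    such actions are skipped and counted, never raised. The realized score
    delta is re-evaluated against the *current* state so the running total
    stays exact even when batching makes a decided move locally worse.

    Returns (joins_applied, leaves_applied, skipped, realized_delta_sum).
    """
    joins = leaves = skipped = 0
    realized = 0.0
    for action in actions:
        x = action.node
        if action.leave_target is not None:
            cid = action.leave_target
            if cid in cover.communities and x in cover.communities[cid]:
                realized += delta_leave(x, cid, cover, ctx)
                cover.remove_member(x, cid)
                leaves += 1
            else:
                skipped += 1
        if action.join_target is not None:
            cid = action.join_target
            if cid in cover.communities and x not in cover.communities[cid]:
                realized += delta_join(x, cid, cover, ctx)
                cover.add_member(x, cid)
                joins += 1
            else:
                skipped += 1
    return joins, leaves, skipped, realized


def _prune_degenerate(cover: Cover) -> int:
    """Remove communities with fewer than two members; return how many."""
    doomed = [cid for cid, members in cover.communities.items() if len(members) < 2]
    for cid in doomed:
        cover.remove_community(cid)
    return len(doomed)


def run_iteration(
    cover: Cover,
    order: list[int],
    config: RunConfig,
    ctx: MetricContext,
    *,
    iteration: int,
    previous_wcc: float,
    running_wcc: float,
) -> tuple[IterationRecord, float]:
    """One full pass over the node order in blocks of ``queue_size``.

    Every block's actions are computed against the frozen block-start cover
    (read-only evaluation), then bulk-applied. Degenerate communities are
    pruned once, after the last block. Returns the iteration record and the
    updated running score.
    """
    q = config.queue_size
    joins = leaves = skipped = 0
    for start in range(0, len(order), q):
        block = order[start : start + q]
        if config.worker_count > 1 and len(block) > 1:
            with ThreadPoolExecutor(max_workers=config.worker_count) as pool:
                actions = list(
                    pool.map(lambda x: best_actions(x, cover, ctx), block)
                )
        else:
            actions = [best_actions(x, cover, ctx) for x in block]
        j, l, s, realized = apply_actions(actions, cover, ctx)
        joins += j
        leaves += l
        skipped += s
        running_wcc += realized

    removed = _prune_degenerate(cover)  # degenerate communities score 0

    rel = abs(running_wcc - previous_wcc) / previous_wcc if previous_wcc > 0 else 0.0
    record = IterationRecord(
        iteration=iteration,
        wcc_hat=running_wcc,
        relative_change=rel,
        joins_applied=joins,
        leaves_applied=leaves,
        actions_skipped=skipped,
        communities_removed=removed,
        community_count=len(cover),
    )
    return record, running_wcc


def run(
    graph: Graph,
    config: RunConfig = RunConfig(),
    seed_cover: Cover | None = None,
    *,
    iteration_callback=None,
) -> tuple[Cover, RunTrace]:
    """Full detection run: preprocess, iterate, stop on relative stagnation.

    ``seed_cover`` replaces the greedy initial clustering when given (e.g. to
    overlap-refine an existing disjoint partition). ``iteration_callback``,
    when set, receives ``(iteration, cover)`` after every iteration (used for
    per-iteration dumps).
    """
    stats = compute_stats(graph)
    ctx = MetricContext(cc_global=stats.cc_global, degrees=stats.d)
    order = node_order(graph, stats)
    cover = seed_cover.copy() if seed_cover is not None else initial_cover(graph, order)

    running = wcc_hat_total(cover, ctx)
    trace = RunTrace(initial_wcc_hat=running)
    iteration = 0
    while config.max_iterations is None or iteration < config.max_iterations:
        iteration += 1
        previous = running
        record, running = run_iteration(
            cover,
            order,
            config,
            ctx,
            iteration=iteration,
            previous_wcc=previous,
            running_wcc=running,
        )
        trace.records.append(record)
        if iteration_callback is not None:
            iteration_callback(iteration, cover)
        if previous <= 0.0:
            break  # nothing to improve relative to; guard against 0-division
        if record.relative_change < config.wcc_threshold:
            break
    return cover, trace


def run_sequential_reference(
    graph: Graph,
    wcc_threshold: float = 0.01,
    max_iterations: int | None = None,
    seed_cover: Cover | None = None,
) -> tuple[Cover, RunTrace]:
    """Straightforward single-node-at-a-time implementation (verification).

    Kept deliberately independent of the batched engine: per node it computes
    both best actions from the current state and applies them immediately
    (leave, then join); the cover score is recomputed from scratch at every
    iteration end instead of being tracked incrementally. The batched engine
    at ``queue_size=1`` must reproduce its covers exactly.
    """
    stats = compute_stats(graph)
    ctx = MetricContext(cc_global=stats.cc_global, degrees=stats.d)
    order = node_order(graph, stats)
    cover = seed_cover.copy() if seed_cover is not None else initial_cover(graph, order)

    previous = wcc_hat_total(cover, ctx)
    trace = RunTrace(initial_wcc_hat=previous)
    iteration = 0
    while max_iterations is None or iteration < max_iterations:
        iteration += 1
        joins = leaves = 0
        for x in order:
            action = best_actions(x, cover, ctx)
            if action.leave_target is not None:
                cover.remove_member(x, action.leave_target)
                leaves += 1
            if action.join_target is not None:
                cover.add_member(x, action.join_target)
                joins += 1
        removed = _prune_degenerate(cover)
        current = wcc_hat_total(cover, ctx)
        rel = abs(current - previous) / previous if previous > 0 else 0.0
        trace.records.append(
            IterationRecord(
                iteration=iteration,
                wcc_hat=current,
                relative_change=rel,
                joins_applied=joins,
                leaves_applied=leaves,
                actions_skipped=0,
                communities_removed=removed,
                community_count=len(cover),
            )
        )
        if previous <= 0.0 or rel < wcc_threshold:
            break
        previous = current
    return cover, trace
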