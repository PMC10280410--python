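# Methods

## Model and procedure

`foxcd` maximizes a triangle-based fitness of an overlapping community
cover over a simple undirected graph G(V, E). The exact score (weighted
community clustering) of a node x in a community C is

    WCC(x, C) = t(x,C)/t(x,V) · vt(x,V) / (|C∖{x}| + vt(x,V∖C)),  t(x,V) > 0

and 0 otherwise, where t(x,S) is the number of triangles through x with both
co-vertices in S and vt(x,S) the number of nodes of S sharing at least one
triangle with x. Community and cover scores are sums over members and
communities. This exact form is implemented as a verification oracle
(`wcc_exact_node` / `wcc_exact_total`); the optimizer runs on a mean-field
estimate, WCC-hat, obtained by three approximations:

1. **In-community triangles.** Assuming the community's internal edges are
   homogeneously distributed with density p = internal_edges / C(|C|, 2),
   the expected triangle count of a node with deg(x,C) in-community edges is
   E[t(x,C)] = C(deg(x,C), 2) · p.
2. **Global triangles.** Analogously E[t(x,V)] = C(deg(x,V), 2) · cc with cc
   the *mean of all local clustering coefficients* (degree-≤1 nodes counted
   as 0). Note this is not transitivity (the triangle/triplet ratio); the
   two differ on inhomogeneous graphs.
3. **vt upper bounds.** vt(x,V) ≤ deg(x,V) and vt(x,V∖C) ≤ deg(x,V∖C) =
   deg(x,V) − deg(x,C); the bounds replace the exact counts.

The same formula scores members and join candidates; for a candidate x ∉ C,
|C∖{x}| = |C| and the community density does not include x. The score is 0
whenever deg(x,C) ≤ 1, deg(x,V) ≤ 1, p = 0 or cc = 0.

**Optimization.** Nodes are visited in a fixed order — local clustering
coefficient descending, degree descending, dense index ascending — computed
once at preprocessing and never re-sorted. The initial cover is the greedy
non-overlapping decomposition (an unassigned node opens a community and
claims its unassigned neighbors); a user-supplied seed cover can replace it.
Per node, the candidate joins are the communities of its neighbors it is not
in, and the candidate leaves its own communities; the best strictly-positive
delta on each side is selected (ties to the lowest community ID). With
queue size q, the actions of q consecutive nodes are computed against the
frozen block-start state and then applied in node order, leave before join
per node; q = 1 reproduces the strictly sequential algorithm, verified
against an independently coded one-node-at-a-time reference. After each
iteration communities with fewer than two members are removed: a candidate
joiner's in-community degree to a singleton is at most 1, so its expected
triangle count — and hence any join gain — is exactly 0. Removing a node's
last community keeps the node; memberless nodes may re-join later.

**Stopping.** The run ends when |ΔWCC-hat| / WCC-hat_prev between
consecutive iterations falls below the threshold (default 0.01; the first
iteration compares against the initial cover). The absolute value is used
because batched updates can transiently lower the score; at q = 1 the
trajectory is provably non-decreasing (only positive deltas apply). A zero
previous score stops the run (division guard), as does `max_iterations`.

## Efficiency and numerical choices

- The cover caches per-community internal edge counts and per-member
  in-community degrees, updated in O(|C|) per move. A join/leave delta is
  evaluated *community-locally*: for any node y in a community C′ ≠ C, no
  ingredient of its WCC-hat term (deg(y,C′), |C′|, p(C′), deg(y,V), cc)
  depends on x's membership in C, so the cover-level delta equals the
  before/after difference of C's community score alone. The test suite
  checks this against full cache-free recomputation to 1e−9.
- The running cover score is updated incrementally with the *realized*
  delta, re-evaluated at apply time (a batched action may be stale), so it
  tracks a from-scratch recomputation to float accumulation error.
- Community sums accumulate in ascending member index; candidate scans run
  in ascending community ID with strict improvement — together with the
  absence of any randomness this makes runs bit-reproducible for a fixed
  (graph, queue size, threshold), independent of worker count. Worker
  threads only evaluate the pure per-node searches of one frozen block.
- Stale batched actions (the node already left / already a member) are
  skipped and counted, never raised. Joins into communities that shrank
  below two members mid-iteration are still applied; pruning happens only at
  iteration end.
- Tie-breaking choices that the underlying method leaves open are fixed for
  reproducibility: node order falls back to the dense index ascending, and
  equal move deltas resolve to the lowest community ID.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `queue_size` | 1 | nodes per frozen-snapshot batch; 1 = sequential semantics; the CLI defaults it to `--workers` |
| `worker_count` | 1 | threads evaluating a batch; never affects results |
| `wcc_threshold` | 0.01 | relative score-change stopping criterion; 0.02 typically saves iterations at slight quality cost |
| `max_iterations` | unlimited | hard cap, useful for profiling |

## Synthetic benchmark generator

`synthetic.generate` plants K communities of given sizes, assigns a
`shared_fraction` slice of each community (its lowest-index members,
deterministically) to the next community as well, and draws intra-community
node pairs with probability `p_in` and all remaining pairs with `p_out`
from a single seeded generator. It emulates the defining feature of
by-bond communities — dense internal connectivity with many closed
triangles over a sparse background, with controlled per-node overlap. It
does **not** emulate heavy-tailed degree distributions, community-size
power laws, or hierarchical/nested ground truth found in real social and
biological networks; passing recovery tests therefore demonstrates
correctness of the optimization machinery on well-separated structure, not
performance on adversarial real-world topologies. The default study
condition used by the recovery tests and the acceptance script is
10 communities × 20 nodes, 10% shared, p_in = 0.9, p_out = 0.01.

## Evaluation

Cover F1 between a detected cover P′ and a reference P is the mean over
detected communities of the best harmonic mean of precision |C∩C′|/|C′| and
recall |C∩C′|/|C|; it is asymmetric and computed with an exact max (no
approximate matching). Per-node overlap statistics report the mean number
of communities per *assigned* node by default, with the all-nodes
denominator exposed alongside, since published overlap figures do not
always state their denominator. An overlapping-NMI distance is deliberately
not implemented; comparison tables can take such values from external
implementations.

## Degenerate inputs and limitations

- Self-loops and duplicate edges are dropped at parse time (counted and
  logged); files with more than two tokens per line are rejected outright
  to catch weighted edge lists early. Weighted and directed graphs are out
  of scope.
- Triangle-free graphs have cc = 0, every score is 0, and the run stops
  after one iteration with the pruned initial cover — the metric simply has
  no signal without triangles.
- Post-processing (duplicate and nested-community removal) is off by
  default because contained communities are sometimes genuine structure;
  nested removal keeps the superset. Splitting internally disconnected
  communities is not implemented.
- The problem sizes used by the test suite and acceptance script (graphs of
  up to a few hundred nodes, tens of replicates) were chosen as the scale
  at which every property can be verified against brute-force oracles;
  the engine itself has no such limits, and the per-move cost is O(|C|)
  plus the candidate scan.
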