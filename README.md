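# foxcd — overlapping community detection by greedy WCC-hat optimization

Many real networks — co-authorship graphs, e-mail networks, protein–protein
interaction maps — organize into *communities of bond*: groups whose members
are densely wired to each other, closing many triangles. Unlike partitions,
such groups overlap: an author belongs to several research groups, a protein
to several complexes. `foxcd` detects overlapping communities in undirected,
unweighted graphs by letting each node greedily join and leave communities so
as to maximize a triangle-based fitness of the whole cover, with optional
batching of node updates so the expensive per-node searches can run in
parallel without changing the (fully deterministic) result.

## The metric and the algorithm

The weighted community clustering score rates how well a node *x* fits a
community *C* by the fraction of its triangles closed inside *C*:

```
WCC(x, C) = t(x,C)/t(x,V) · vt(x,V) / (|C∖{x}| + vt(x,V∖C))        if t(x,V) > 0
```

where `t(x,S)` counts triangles through *x* with both co-vertices in *S* and
`vt(x,S)` counts nodes in *S* sharing a triangle with *x*. Community and
cover scores are the sums over members and communities. Exact triangle
counting per candidate move is expensive, so the optimizer uses a mean-field
estimate (WCC-hat): assuming edges inside *C* are homogeneous with density
*p*, `E[t(x,C)] = C(deg(x,C),2)·p` and `E[t(x,V)] = C(deg(x,V),2)·cc` with
*cc* the mean local clustering coefficient, and the `vt` terms are replaced
by their degree upper bounds:

```
WCC-hat(x, C) = E[t(x,C)]/E[t(x,V)] · deg(x,V) / (|C∖{x}| + deg(x,V∖C))
```

The optimizer visits nodes in a fixed order (decreasing local clustering
coefficient, then decreasing degree, then index), starting from a greedy
non-overlapping cover. Per node it evaluates the best community to *join*
(among its neighbors' communities) and the best to *leave* (among its own),
applying only moves with a strictly positive score delta. With queue size
*q* > 1, the best actions for *q* nodes are computed against one frozen
snapshot and bulk-applied — the batching that makes the search parallel.
Communities that degenerate below two members are pruned after each
iteration (they are provably un-joinable), and the run stops when the
relative score change between iterations falls below a threshold (default
0.01).

## Worked example

```python
from foxcd import PlantedSpec, RunConfig, cover_f1, cover_stats, generate, run

spec = PlantedSpec(n_communities=10, community_size=20, shared_fraction=0.1,
                   p_in=0.9, p_out=0.01, seed=1)
graph, truth = generate(spec)
cover, trace = run(graph, RunConfig(queue_size=1))
print(len(cover), round(cover_f1(cover, truth), 3))
```

Running `python examples/01_planted_recovery.py` (which does the above and
prints the summary) gives:

```
graph: 200 nodes, 2244 edges
converged after 4 iterations
detected 15 communities (mean size 22.0, mean memberships per node 1.65)
cover F1 vs planted truth: 1.000
```

Cover F1 = 1.0 means every detected community coincides exactly with a
planted one; the count above 10 reflects planted communities rediscovered
through the overlap (removable with `foxcd.postprocess`). The other
examples walk through the metric by hand, the convergence trace, cover
cleanup, and running on a real edge list you supply locally.

The same pipeline is available from a shell:

```
foxcd simulate --communities 10 --size 20 --shared 0.1 --seed 1 --out-prefix bench
foxcd run --input bench.edges --output-dir out --queue-size 4 --workers 4
foxcd evaluate --detected out/final.cover --truth bench.truth --graph bench.edges
```

`foxcd run` writes `final.cover` (one community per line, original node
labels) and `trace.json`, a manifest with the input digest, configuration
and the per-iteration score trajectory; the outputs are byte-identical for
any `--workers` at a fixed queue size.

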