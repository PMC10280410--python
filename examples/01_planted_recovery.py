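"""Detect planted overlapping communities and score the recovery.

Builds a 200-node benchmark graph of 10 planted communities (20 nodes each,
10% of each community shared with the next one, intra-community edge
probability 0.9 over a 0.01 background), runs the detector, and compares the
result to the planted ground truth.
"""

from foxcd import PlantedSpec, RunConfig, cover_f1, cover_stats, generate, run

spec = PlantedSpec(
    n_communities=10, community_size=20, shared_fraction=0.1,
    p_in=0.9, p_out=0.01, seed=1,
)
graph, truth = generate(spec)
print(f"graph: {graph.n_nodes} nodes, {graph.n_edges} edges")

cover, trace = run(graph, RunConfig(queue_size=1))
stats = cover_stats(cover, graph)
f1 = cover_f1(cover, truth)

print(f"converged after {trace.iterations} iterations")
print(f"detected {stats.community_count} communities "
      f"(mean size {stats.size_mean:.1f}, mean memberships per node "
      f"{stats.mean_memberships:.2f})")
print(f"cover F1 vs planted truth: {f1:.3f}")
print()
print("An F1 of 1.0 means every detected community coincides exactly with a")
print("planted one; counts above 10 mean some planted communities were")
print("discovered more than once through the planted overlap (duplicates can")
print("be removed with foxcd.postprocess).")
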