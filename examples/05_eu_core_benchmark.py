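"""Run the detector on a real SNAP edge list (supplied locally).

Usage:
    python examples/05_eu_core_benchmark.py path/to/email-Eu-core.txt

The SNAP e-mail network of a European research institution (1,005 nodes,
25,571 edges after collapsing duplicates) is a classic small benchmark for
overlapping community detection; with the default threshold 0.01 and queue
size 1 the detector reports the community count, size range and the mean
number of communities per node. Nothing is downloaded — point the script at
any whitespace-separated edge list you already have.
"""

import sys

from foxcd import RunConfig, cover_stats, read_edge_list, run

if len(sys.argv) != 2:
    sys.exit(__doc__)

graph = read_edge_list(sys.argv[1])
print(f"graph: {graph.n_nodes} nodes, {graph.n_edges} edges "
      f"({graph.dropped_duplicates} duplicate edges and "
      f"{graph.dropped_self_loops} self-loops dropped)")

cover, trace = run(graph, RunConfig(queue_size=1, wcc_threshold=0.01))
stats = cover_stats(cover, graph)

print(f"converged after {trace.iterations} iterations")
print(f"{stats.community_count} communities, sizes "
      f"{stats.size_min}..{stats.size_max} (mean {stats.size_mean:.1f})")
print(f"mean communities per assigned node: {stats.mean_memberships:.2f} "
      f"({stats.memberless_count} memberless nodes)")
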