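"""Optional cleanup of a detected cover: duplicates and nested communities.

Overlap optimization can rediscover the same community from different
starting nodes, or keep a subgroup alongside its containing group. Both are
sometimes genuine structure, so cleanup is opt-in.
"""

from foxcd import Cover, Graph, dedupe, postprocess, remove_nested

graph = Graph.from_edges(
    [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e"), ("c", "e")]
)
ids = graph.label_index
cover = Cover.from_communities(
    graph,
    [
        {ids["a"], ids["b"], ids["c"]},
        {ids["a"], ids["b"], ids["c"]},          # duplicate
        {ids["a"], ids["b"]},                    # nested in the triangle
        {ids["c"], ids["d"], ids["e"]},
    ],
)

show = lambda c: sorted(sorted(graph.labels[x] for x in m) for m in c.communities.values())
print("raw cover:          ", show(cover))
print("after dedupe:       ", show(dedupe(cover)))
print("after nested removal:", show(remove_nested(dedupe(cover))))
print("postprocess() chains both:", show(postprocess(cover)))
print()
print("The duplicate triangle collapses to one community and the contained")
print("pair {a,b} disappears; the two genuine overlapping triangles remain.")
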