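"""The metric core: mean-field score, exact oracle, move deltas, caches."""

import random

import pytest

from foxcd import (
    Cover,
    MetricContext,
    community_density,
    compute_stats,
    delta_join,
    delta_leave,
    wcc_exact_node,
    wcc_exact_total,
    wcc_hat_community,
    wcc_hat_node,
    wcc_hat_total,
)
from foxcd.graph_io import Graph

from conftest import naive_wcc_hat_total, random_cover, random_graph


def ctx_for(graph: Graph) -> MetricContext:
    stats = compute_stats(graph)
    return MetricContext(cc_global=stats.cc_global, degrees=stats.d)


class TestCommunityDensity:
    def test_triangle_is_full(self, triangle):
        cover = Cover.from_communities(triangle, [{0, 1, 2}])
        assert community_density(cover, 0) == 1.0

    def test_two_of_three_edges(self):
        g = Graph.from_edges([("a", "b"), ("b", "c")])
        cover = Cover.from_communities(g, [{0, 1, 2}])
        assert community_density(cover, 0) == pytest.approx(2 / 3)

    def test_singleton_is_zero(self, triangle):
        cover = Cover.from_communities(triangle, [{0}])
        assert community_density(cover, 0) == 0.0


class TestMeanFieldNodeScore:
    def test_worked_example(self, kite):
        """Joining candidate d against the triangle community scores 0.8."""
        cover = Cover.from_communities(kite, [{0, 1, 2}])
        d = kite.label_index["d"]
        assert wcc_hat_node(d, 0, cover, ctx_for(kite)) == pytest.approx(
            0.8, abs=1e-12
        )

    def test_low_in_degree_vanishes(self, kite):
        # c's single edge into {a, d} cannot close a triangle in expectation
        cover = Cover.from_communities(kite, [{0, 3}])
        c = kite.label_index["c"]
        assert wcc_hat_node(c, 0, cover, ctx_for(kite)) == 0.0

    def test_isolated_node_zero_branch(self):
        g = Graph.from_edges([("a", "b"), ("b", "c"), ("a", "c")], labels="abcz")
        cover = Cover.from_communities(g, [{0, 1, 2}])
        z = g.label_index["z"]
        assert wcc_hat_node(z, 0, cover, ctx_for(g)) == 0.0

    def test_member_vs_candidate_set_size(self, triangle):
        """|C \\ {x}| excludes x only when x is a member."""
        cover = Cover.from_communities(triangle, [{0, 1, 2}])
        ctx = ctx_for(triangle)
        # member of the full K3 community: per-node score is exactly 1
        assert wcc_hat_node(0, 0, cover, ctx) == pytest.approx(1.0, abs=1e-12)


class TestMeanFieldAggregates:
    def test_singleton_community_scores_zero(self, triangle):
        cover = Cover.from_communities(triangle, [{0}])
        assert wcc_hat_community(0, cover, ctx_for(triangle)) == 0.0

    def test_symmetry_in_k3(self, triangle):
        cover = Cover.from_communities(triangle, [{0, 1, 2}])
        ctx = ctx_for(triangle)
        per_node = wcc_hat_node(0, 0, cover, ctx)
        assert wcc_hat_community(0, cover, ctx) == pytest.approx(3 * per_node)

    def test_additivity_over_disjoint_triangles(self, two_triangles):
        cover = Cover.from_communities(two_triangles, [{0, 1, 2}, {3, 4, 5}])
        ctx = ctx_for(two_triangles)
        total = wcc_hat_total(cover, ctx)
        assert total == pytest.approx(2 * wcc_hat_community(0, cover, ctx))

    def test_empty_cover(self, triangle):
        cover = Cover(triangle)
        assert wcc_hat_total(cover, ctx_for(triangle)) == 0.0

    def test_matches_naive_recomputation(self):
        for seed in range(5):
            g = random_graph(60, 5.0, seed=seed)
            cover = random_cover(g, 6, seed=seed + 100)
            ctx = ctx_for(g)
            assert wcc_hat_total(cover, ctx) == pytest.approx(
                naive_wcc_hat_total(cover, ctx.cc_global), abs=1e-9
            )

    def test_clique_cover_reaches_node_count(self):
        """On K_n covered by {V}: p = cc = 1 and every bound is tight,
        so exact WCC and the mean-field score coincide at exactly n."""
        n = 6
        labels = [str(i) for i in range(n)]
        edges = [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]
        g = Graph.from_edges(edges)
        cover = Cover.from_communities(g, [set(range(n))])
        assert wcc_hat_total(cover, ctx_for(g)) == pytest.approx(n, abs=1e-12)
        assert wcc_exact_total(cover, g) == pytest.approx(n, abs=1e-12)


class TestExactOracle:
    def test_k3_member(self, triangle):
        cover = Cover.from_communities(triangle, [{0, 1, 2}])
        assert wcc_exact_node(0, 0, cover, triangle) == pytest.approx(1.0)
        assert wcc_exact_total(cover, triangle) == pytest.approx(3.0)

    def test_no_triangles_is_zero(self, five_path):
        cover = Cover.from_communities(five_path, [{0, 1, 2}])
        assert wcc_exact_node(1, 0, cover, five_path) == 0.0

    def test_worked_example_outsider(self, kite):
        # t(d,C)=1, t(d,V)=1, vt(d,V)=2, |C\{d}|=3, vt(d,V\C)=0 -> 2/3
        cover = Cover.from_communities(kite, [{0, 1, 2}])
        d = kite.label_index["d"]
        assert wcc_exact_node(d, 0, cover, kite) == pytest.approx(2 / 3, abs=1e-12)

    def test_additive_over_components(self, two_triangles):
        cover = Cover.from_communities(two_triangles, [{0, 1, 2}, {3, 4, 5}])
        assert wcc_exact_total(cover, two_triangles) == pytest.approx(6.0)


class TestMoveDeltas:
    def test_join_singleton_is_zero(self, kite):
        cover = Cover.from_communities(kite, [{2}])
        d = kite.label_index["d"]
        assert delta_join(d, 0, cover, ctx_for(kite)) == 0.0

    def test_join_worked_example_matches_two_evaluations(self, kite):
        cover = Cover.from_communities(kite, [{0, 1, 2}])
        ctx = ctx_for(kite)
        d = kite.label_index["d"]
        before = wcc_hat_community(0, cover, ctx)
        expanded = Cover.from_communities(kite, [{0, 1, 2, d}])
        after = wcc_hat_community(0, expanded, ctx)
        assert delta_join(d, 0, cover, ctx) == pytest.approx(after - before, abs=1e-12)

    def test_leave_sole_member_is_zero(self, triangle):
        cover = Cover.from_communities(triangle, [{0}])
        assert delta_leave(0, 0, cover, ctx_for(triangle)) == 0.0

    def test_contract_violations(self, triangle):
        cover = Cover.from_communities(triangle, [{0, 1}])
        ctx = ctx_for(triangle)
        with pytest.raises(ValueError):
            delta_join(0, 0, cover, ctx)
        with pytest.raises(ValueError):
            delta_leave(2, 0, cover, ctx)

    def test_deltas_match_full_recomputation(self):
        """Cached community-local deltas == naive before/after full totals."""
        rng = random.Random(42)
        for trial in range(25):
            g = random_graph(40, 5.0, seed=trial)
            cover = random_cover(g, 5, seed=trial + 50)
            ctx = ctx_for(g)
            base = naive_wcc_hat_total(cover, ctx.cc_global)
            for _ in range(8):
                x = rng.randrange(g.n_nodes)
                cid = rng.choice(sorted(cover.communities))
                mutated = cover.copy()
                if x in cover.communities[cid]:
                    d = delta_leave(x, cid, cover, ctx)
                    mutated.remove_member(x, cid)
                else:
                    d = delta_join(x, cid, cover, ctx)
                    mutated.add_member(x, cid)
                naive = naive_wcc_hat_total(mutated, ctx.cc_global) - base
                assert d == pytest.approx(naive, abs=1e-9)

    def test_leave_reverses_join(self):
        rng = random.Random(7)
        g = random_graph(30, 4.0, seed=1)
        cover = random_cover(g, 4, seed=2)
        ctx = ctx_for(g)
        for _ in range(30):
            x = rng.randrange(g.n_nodes)
            cid = rng.choice(sorted(cover.communities))
            if x in cover.communities[cid]:
                continue
            d_join = delta_join(x, cid, cover, ctx)
            joined = cover.copy()
            joined.add_member(x, cid)
            assert delta_leave(x, cid, joined, ctx) == pytest.approx(
                -d_join, abs=1e-12
            )


class TestCacheCoherence:
    def test_caches_survive_arbitrary_mutation_sequences(self):
        rng = random.Random(3)
        g = random_graph(50, 5.0, seed=8)
        cover = random_cover(g, 6, seed=9)
        for _ in range(300):
            cids = sorted(cover.communities)
            if not cids:
                break
            x = rng.randrange(g.n_nodes)
            cid = rng.choice(cids)
            roll = rng.random()
            if roll < 0.45 and x not in cover.communities[cid]:
                cover.add_member(x, cid)
            elif roll < 0.9 and x in cover.communities[cid]:
                cover.remove_member(x, cid)
            elif roll >= 0.97:
                cover.remove_community(cid)
        internal, indeg = cover.rebuild_caches()
        assert cover.internal_edges == internal
        assert cover.in_degree == indeg
        for cid, members in cover.communities.items():
            for x in members:
                assert cid in cover.memberships[x]
                assert 0 <= cover.in_degree[cid][x] <= min(
                    g.degree(x), len(members) - 1
                )

    def test_scores_are_non_negative(self):
        g = random_graph(40, 5.0, seed=13)
        cover = random_cover(g, 5, seed=14)
        ctx = ctx_for(g)
        assert wcc_hat_total(cover, ctx) >= 0.0
        assert wcc_exact_total(cover, g) >= 0.0
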