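"""Hub filtering, hit-edge counting, the degree-preserving shuffle null,
and hypergeometric gene-set enrichment."""

import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from chemoscreen import (
    GeneSet,
    GeneSetCollection,
    ValidationError,
    count_hit_edges,
    filter_hubs,
    gene_set_enrichment,
    shuffle_test,
)


def star(n):
    return nx.star_graph(n)  # node 0 is the hub with degree n


class TestFilterHubs:
    def test_degree_at_threshold_removed_below_retained(self):
        g = nx.Graph()
        g.add_edges_from(("hub", f"x{i}") for i in range(200))
        g.add_edges_from(("mid", f"y{i}") for i in range(199))
        net, hits, removed = filter_hubs(g, {"hub", "mid"}, max_partners=200)
        assert removed == ["hub"]
        assert hits == {"mid"}
        assert "hub" not in net and "mid" in net

    def test_no_hubs_identity(self):
        g = nx.path_graph(4)
        net, hits, removed = filter_hubs(g, {0, 3}, max_partners=200)
        assert removed == [] and hits == {0, 3} and net is g

    def test_non_hit_hubs_are_kept(self):
        g = star(300)
        net, hits, removed = filter_hubs(g, {1, 2}, max_partners=200)
        assert removed == [] and 0 in net


class TestCountHitEdges:
    @pytest.mark.parametrize("hits,expected", [
        ({"A", "B"}, 1), ({"A", "B", "C"}, 3), ({"A"}, 0),
    ])
    def test_triangle(self, hits, expected):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        assert count_hit_edges(g, hits) == expected

    def test_all_nodes_counts_every_edge(self):
        g = nx.erdos_renyi_graph(15, 0.3, seed=1)
        assert count_hit_edges(g, set(g.nodes)) == g.number_of_edges()

    def test_absent_hits_dropped_with_warning(self, caplog):
        g = nx.Graph([("A", "B")])
        with caplog.at_level("WARNING"):
            assert count_hit_edges(g, {"A", "B", "Z"}) == 1
        assert any("absent" in r.message for r in caplog.records)


class TestShuffleTest:
    def test_two_edge_closed_form(self):
        """Disjoint edges A-B, C-D with hit {A}: E[S] = 1*1/4 = 0.25."""
        g = nx.Graph([("A", "B"), ("C", "D")])
        res = shuffle_test(g, {"A"}, n_shuffles=100_000, seed=0)
        assert res.expected_null == pytest.approx(0.25)
        se = res.null_counts.std(ddof=1) / math.sqrt(res.n_shuffles)
        assert abs(res.null_counts.mean() - 0.25) < 3 * se

    def test_mc_mean_matches_dh2_over_dtotal_on_random_graphs(self):
        for seed in range(3):
            g = nx.erdos_renyi_graph(20, 0.25, seed=seed)
            hits = set(list(g.nodes)[:6])
            res = shuffle_test(g, hits, n_shuffles=20_000, seed=seed,
                               max_partners=None)
            se = res.null_counts.std(ddof=1) / math.sqrt(res.n_shuffles)
            assert abs(res.null_counts.mean() - res.expected_null) < 3 * se

    def test_null_distribution_matches_exhaustive_enumeration(self):
        """On a <=5-node graph, enumerate every stub-replacement outcome."""
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")])
        hits = {"A", "C"}
        nodes = sorted(g.nodes)
        deg = {v: g.degree[v] for v in nodes}
        total = sum(deg.values())
        n_stubs = deg["A"] + deg["C"]
        exact = Counter()
        for outcome in itertools.product(nodes, repeat=n_stubs):
            prob = math.prod(deg[v] / total for v in outcome)
            exact[sum(v in hits for v in outcome)] += prob
        res = shuffle_test(g, hits, n_shuffles=100_000, seed=3,
                           max_partners=None)
        empirical = Counter(res.null_counts.tolist())
        tv = 0.5 * sum(
            abs(exact.get(s, 0.0) - empirical.get(s, 0) / res.n_shuffles)
            for s in range(n_stubs + 1)
        )
        assert tv < 0.02

    def test_deterministic_and_p_never_zero(self):
        g = nx.erdos_renyi_graph(15, 0.3, seed=2)
        hits = set(list(g.nodes)[:5])
        r1 = shuffle_test(g, hits, n_shuffles=1000, seed=9)
        r2 = shuffle_test(g, hits, n_shuffles=1000, seed=9)
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)
        assert r1.empirical_p >= 1 / 1001

    def test_edge_variant_redirects_each_hit_edge_once(self):
        g = nx.Graph([("A", "B"), ("C", "D"), ("A", "C")])
        res = shuffle_test(g, {"A", "C"}, n_shuffles=1000, seed=1,
                           max_partners=None, variant="edge")
        # D_H = 4 stubs, minus the A-C edge counted from both sides -> 3 draws
        assert res.null_counts.max() <= 3
        assert res.variant == "edge"

    def test_empty_hits_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValidationError):
            shuffle_test(g, set(), n_shuffles=1000, seed=0)


def _collection(*sets):
    return GeneSetCollection([GeneSet(f"T{i}", f"term{i}", frozenset(s))
                              for i, s in enumerate(sets, 1)])


def hypergeom_tail_enumeration(overlap, universe, term, hits):
    """P(X >= overlap) by explicit summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(overlap, min(term, hits) + 1):
        total += (math.comb(term, x) * math.comb(universe - term, hits - x)
                  / math.comb(universe, hits))
    return total


class TestGeneSetEnrichment:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {"g0", "g1", "g2", "g3", "g4"}
        coll = _collection({"g0", "g1", "g2", "g3"})
        out = gene_set_enrichment(hits, universe, coll)
        assert out["overlap"].iloc[0] == 4
        assert out["p_value"].iloc[0] == pytest.approx(16 / 15504)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        out = gene_set_enrichment({"g0", "g1"}, universe,
                                  _collection({"g8", "g9"}))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_term_equal_to_universe_saturates(self):
        universe = {f"g{i}" for i in range(8)}
        out = gene_set_enrichment({"g0", "g1"}, universe, _collection(universe))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_exact_tail_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_universe = int(rng.integers(5, 31))
            universe = {f"g{i}" for i in range(n_universe)}
            hits = set(rng.choice(sorted(universe),
                                  size=rng.integers(1, n_universe + 1),
                                  replace=False))
            term = set(rng.choice(sorted(universe),
                                  size=rng.integers(1, n_universe + 1),
                                  replace=False))
            out = gene_set_enrichment(hits, universe, _collection(term))
            expected = hypergeom_tail_enumeration(
                len(term & hits), n_universe, len(term), len(hits))
            assert out["p_value"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            gene_set_enrichment({"a"}, set(), _collection({"a"}))

    def test_fdr_column_is_bh_over_terms(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(5)}
        coll = _collection({"g0", "g1", "g2", "g3"}, {"g15", "g16"},
                           {"g0", "g10"})
        out = gene_set_enrichment(hits, universe, coll)
        assert (out["fdr"] >= out["p_value"] - 1e-12).all()
        assert (out["p_value"].diff().dropna() >= 0).all()  # sorted by p
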