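from __future__ import annotations

import itertools

import networkx as nx
import pytest

from _oracles import brute_betweenness, hypergeom_upper_tail
from conftest import SMALL_BATTERY
from metmod.enrichment import (
    PathwayGraph,
    enrich,
    expected_hits,
    hypergeom_pvalue,
    impact,
    relative_betweenness,
)
from metmod.synthetic import generate_pathway_graph


def pg_from_edges(name, edges, nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(nodes)
    return PathwayGraph(name=name, graph=g)


class TestExpectedHits:
    @pytest.mark.parametrize(
        "total,frac,expected",
        [(67, 0.02, 1.34), (32, 0.02, 0.64), (11, 0.02, 0.22), (4, 0.02, 0.08), (100, 0.0, 0.0)],
    )
    def test_published_expected_column(self, total, frac, expected):
        assert expected_hits(total, frac) == expected

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            expected_hits(10, 1.5)


class TestHypergeomPvalue:
    def test_all_hits_from_half_universe(self):
        assert hypergeom_pvalue(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_zero_hits_tail_is_one(self):
        assert hypergeom_pvalue(20, 5, 4, 0) == pytest.approx(1.0)

    def test_small_enumeration_example(self):
        assert hypergeom_pvalue(4, 2, 2, 1) == pytest.approx(5 / 6)

    def test_matches_enumeration_up_to_n12(self):
        cases = [
            (N, K, n, k)
            for N in (6, 9, 12)
            for K in (2, N // 2)
            for n in (2, N // 3)
            for k in range(0, min(K, n) + 1)
        ]
        for N, K, n, k in cases:
            assert hypergeom_pvalue(N, K, n, k) == pytest.approx(
                hypergeom_upper_tail(N, K, n, k), abs=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 5, 3, 4)


class TestRelativeBetweenness:
    def test_path_of_four_interior_halves(self):
        pg = generate_pathway_graph(4, "path")
        imp = relative_betweenness(pg)
        assert imp["C2"] == imp["C3"] == 0.5
        assert imp["C1"] == imp["C4"] == 0.0

    def test_star_hub_takes_all(self):
        pg = generate_pathway_graph(8, "star")
        imp = relative_betweenness(pg)
        assert imp["C1"] == 1.0 and all(imp[f"C{i}"] == 0.0 for i in range(2, 9))

    def test_triangle_uniform_fallback(self):
        pg = pg_from_edges("tri", [("a", "b"), ("b", "c"), ("a", "c")])
        assert relative_betweenness(pg) == {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}

    def test_importances_sum_to_one(self):
        for name, (n, edges) in SMALL_BATTERY.items():
            pg = pg_from_edges(name, [(str(u), str(v)) for u, v in edges],
                               nodes=[str(i) for i in range(n)])
            assert sum(relative_betweenness(pg).values()) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        for name, (n, edges) in SMALL_BATTERY.items():
            pg = pg_from_edges(name, [(str(u), str(v)) for u, v in edges],
                               nodes=[str(i) for i in range(n)])
            raw = brute_betweenness(edges, n)
            total = sum(raw.values())
            got = relative_betweenness(pg)
            if total == 0:
                assert all(v == pytest.approx(1 / n) for v in got.values())
            else:
                for i in range(n):
                    assert got[str(i)] == pytest.approx(raw[i] / total, abs=1e-12)


class TestImpact:
    def test_single_interior_hit_on_linear_pathway(self):
        pg = generate_pathway_graph(4, "path")
        assert impact(pg, {"C2"}) == 0.50

    def test_all_hit_is_one(self):
        pg = generate_pathway_graph(6, "er", seed=3)
        assert impact(pg, set(pg.members)) == 1.0

    def test_end_nodes_only_is_zero(self):
        pg = generate_pathway_graph(4, "path")
        assert impact(pg, {"C1", "C4"}) == 0.0

    def test_hit_outside_pathway_rejected(self):
        pg = generate_pathway_graph(4, "path")
        with pytest.raises(ValueError):
            impact(pg, {"Z"})

    def test_monotone_in_hit_set(self):
        pg = generate_pathway_graph(7, "er", seed=2)
        members = sorted(pg.members)
        for size in range(1, len(members)):
            assert impact(pg, members[: size + 1]) >= impact(pg, members[:size])


class TestEnrich:
    def build_battery(self):
        # 8 linear pathways hit on an interior compound (impact 0.50) and
        # 19 hit only on an end compound (impact 0.00): exactly 8 above 0.10.
        pathways, query = [], set()
        for i in range(8):
            g = nx.path_graph([f"p{i}_{j}" for j in range(4)])
            pathways.append(PathwayGraph(name=f"sig{i}", graph=g))
            query.add(f"p{i}_1")
        for i in range(19):
            g = nx.path_graph([f"q{i}_{j}" for j in range(4)])
            pathways.append(PathwayGraph(name=f"bg{i}", graph=g))
            query.add(f"q{i}_0")
        return query, pathways

    def test_exactly_eight_significant_of_27(self):
        query, pathways = self.build_battery()
        results = enrich(query, pathways, universe_size=200, threshold=0.10)
        assert len(results) == 27
        assert sum(r.significant for r in results) == 8
        assert [r.impact for r in results[:8]] == [0.50] * 8

    def test_disjoint_query_empty_result(self):
        _, pathways = self.build_battery()
        assert enrich({"nowhere"}, pathways, universe_size=100) == []

    def test_fully_hit_pathway(self):
        pg = generate_pathway_graph(5, "path")
        (r,) = enrich(set(pg.members), [pg], universe_size=50)
        assert r.impact == 1.0 and r.significant and r.hits == 5

    def test_expected_uses_query_fraction(self):
        pg = generate_pathway_graph(4, "path")
        (r,) = enrich({"C2"}, [pg], universe_size=100, query_fraction=0.02)
        assert r.expected == 0.08 and r.total == 4

    def test_universe_smaller_than_query_rejected(self):
        pg = generate_pathway_graph(4, "path")
        with pytest.raises(ValueError):
            enrich({"C1", "C2", "C3"}, [pg], universe_size=2)

    def test_sorted_by_impact_desc(self):
        query, pathways = self.build_battery()
        results = enrich(query, pathways, universe_size=200)
        impacts = [r.impact for r in results]
        assert impacts == sorted(impacts, reverse=True)
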