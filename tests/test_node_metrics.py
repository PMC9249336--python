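"""Classical node metrics against brute force; q-DC and cycle ranking."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ppitopo.clique_complex import build_clique_complex
from ppitopo.homology_gf2 import homology_generators_1
from ppitopo.node_metrics import (
    assortativity,
    betweenness,
    closeness,
    clustering,
    degree,
    node_metric_table,
    q_dc,
    rank_cycles,
)


@pytest.fixture(scope="module")
def fixture_graph() -> nx.Graph:
    return nx.erdos_renyi_graph(10, 0.4, seed=21)


class TestClassicalMetrics:
    def test_degree_star_and_isolate(self):
        g = nx.star_graph(3)
        g.add_node("iso")
        d = degree(g)
        assert d[0] == 3 and d["iso"] == 0

    def test_clustering_known_values(self):
        assert clustering(nx.complete_graph(3))[0] == 1.0
        assert clustering(nx.path_graph(3))[1] == 0.0  # 2 non-adjacent neighbors
        assert clustering(nx.path_graph(2))[0] == 0.0  # degree < 2

    def test_clustering_matches_neighbor_pair_count(self, fixture_graph):
        got = clustering(fixture_graph)
        for v in fixture_graph.nodes:
            nbrs = list(fixture_graph[v])
            k = len(nbrs)
            if k < 2:
                assert got[v] == 0.0
                continue
            e = sum(
                1 for a, b in itertools.combinations(nbrs, 2) if fixture_graph.has_edge(a, b)
            )
            assert got[v] == pytest.approx(2 * e / (k * (k - 1)))

    def test_betweenness_path_center_and_leaves(self):
        b = betweenness(nx.path_graph(3))
        assert b[1] == 1.0
        assert b[0] == b[2] == 0.0

    def test_betweenness_matches_geodesic_enumeration(self, fixture_graph):
        got = betweenness(fixture_graph)
        n = fixture_graph.number_of_nodes()
        nodes = list(fixture_graph.nodes)
        brute = {v: 0.0 for v in nodes}
        for s, t in itertools.combinations(nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(fixture_graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                frac = sum(1 for p in paths if v in p) / len(paths)
                brute[v] += frac
        norm = (n - 1) * (n - 2) / 2
        for v in nodes:
            assert got[v] == pytest.approx(brute[v] / norm)

    def test_closeness_star_center_and_isolate(self):
        g = nx.star_graph(3)
        assert closeness(g)[0] == pytest.approx(1.0)
        g.add_node("iso")
        assert closeness(g)["iso"] == 0.0

    def test_closeness_matches_bfs_reciprocals(self, fixture_graph):
        got = closeness(fixture_graph)
        n = fixture_graph.number_of_nodes()
        for v in fixture_graph.nodes:
            dists = nx.single_source_shortest_path_length(fixture_graph, v)
            s = sum(1.0 / d for u, d in dists.items() if u != v)
            assert got[v] == pytest.approx(s / (n - 1))

    def test_assortativity_degenerate_cases(self):
        # all partners share one target value -> zero variance -> undefined
        star = nx.star_graph(3)
        a = assortativity(star, "degree")
        assert math.isnan(a[0])
        # two nodes: a single partner point, correlation undefined
        two = nx.path_graph(2)
        assert all(math.isnan(x) for x in assortativity(two, "degree").values())

    def test_assortativity_matches_direct_correlation(self, fixture_graph):
        got = assortativity(fixture_graph, "degree")
        deg = dict(fixture_graph.degree())
        nodes = list(fixture_graph.nodes)
        for v in nodes:
            others = [u for u in nodes if u != v]
            dists = nx.single_source_shortest_path_length(fixture_graph, v)
            x = np.array([1.0 / dists[u] if u in dists else 0.0 for u in others])
            y = np.array([deg[u] for u in others])
            if x.std() == 0 or y.std() == 0:
                assert math.isnan(got[v])
            else:
                assert got[v] == pytest.approx(float(np.corrcoef(x, y)[0, 1]))


class TestQDC:
    def test_single_square_everyone_on_one_cycle(self):
        dc = q_dc(nx.cycle_graph(4), 1)
        assert all(v == 1 for v in dc.values())

    def test_zero_when_no_cavities(self):
        dc = q_dc(nx.path_graph(5), 1)
        assert all(v == 0 for v in dc.values())

    def test_detour_node_credited_through_variant(self, fig_two_cavity_graph):
        dc = q_dc(fig_two_cavity_graph, 1)
        # 3 and 4 sit on both cavities; 6 is only on the homologous detour
        assert dc[3] == dc[4] == 2
        assert dc[5] == dc[7] == 1
        assert dc[6] == 1
        assert dc[1] == dc[2] == 1

    def test_counted_cycles_have_at_least_four_nodes(self, small_graph_suite):
        """Triangles are filled in a flag complex, so every 1-cavity cycle
        has >= 4 nodes and total involvement is >= 4 * betti_1."""
        from ppitopo.homology_gf2 import betti_numbers

        for g in small_graph_suite:
            c = build_clique_complex(g)
            gens = homology_generators_1(c)
            for rep in gens:
                assert len(rep.nodes) >= 4
            betti = betti_numbers(c).betti
            b1 = betti[1] if len(betti) > 1 else 0
            dc = q_dc(g, 1, generators=gens)
            assert sum(dc.values()) >= 4 * b1


class TestRankCycles:
    def test_uniform_dc_gives_rank_one(self):
        g = nx.cycle_graph(4)
        gens = homology_generators_1(build_clique_complex(g))
        ranked = rank_cycles(gens, q_dc(g, 1, generators=gens))
        assert len(ranked) == 1
        assert ranked[0].rank_value == pytest.approx(1.0)

    def test_disjoint_squares_tie_broken_lexicographically(self):
        g = nx.disjoint_union(nx.cycle_graph(4), nx.cycle_graph(4))
        gens = homology_generators_1(build_clique_complex(g))
        ranked = rank_cycles(gens, q_dc(g, 1, generators=gens))
        assert [r.rank_value for r in ranked] == [1.0, 1.0]
        assert ranked[0].node_list < ranked[1].node_list

    def test_figure_eight_shared_vertex_raises_rank(self):
        """Two squares sharing one vertex: the shared vertex has dc 2, the
        six others dc 1, so each cycle's mean is (2 + 3)/4 = 5/4."""
        g = nx.Graph(
            [(0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (4, 5), (5, 6), (6, 0)]
        )
        gens = homology_generators_1(build_clique_complex(g))
        dc = q_dc(g, 1, generators=gens)
        assert dc[0] == 2
        ranked = rank_cycles(gens, dc)
        assert [r.rank_value for r in ranked] == [pytest.approx(1.25)] * 2

    def test_empty_input(self):
        assert rank_cycles([], {}) == []


def test_node_metric_table_columns_and_rows(fig_two_cavity_graph):
    table = node_metric_table(fig_two_cavity_graph)
    assert len(table) == fig_two_cavity_graph.number_of_nodes()
    assert list(table.columns) == [
        "node",
        "degree",
        "clustering",
        "betweenness",
        "closeness",
        "assortativity_degree",
        "assortativity_closeness",
        "assortativity_betweenness",
        "dc1",
    ]
    row6 = table[table["node"] == 6].iloc[0]
    assert row6["dc1"] == 1
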