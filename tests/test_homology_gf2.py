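"""GF(2) homology: boundary maps, Betti numbers, cycle representatives."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import dense_betti
from ppitopo.clique_complex import build_clique_complex
from ppitopo.homology_gf2 import (
    Chain,
    betti_numbers,
    boundary_matrix,
    homology_generators_1,
    is_boundary,
)


class TestBoundaryMap:
    def test_edge_boundary_is_its_endpoints(self):
        c = build_clique_complex(nx.Graph([(1, 2)]))
        bm = boundary_matrix(c, 1)
        assert bm.shape == (2, 1)
        assert bm.columns == [0b11]

    def test_triangle_boundary_is_its_three_edges(self):
        chain = Chain(2, frozenset({(1, 2, 3)}))
        assert chain.boundary().simplexes == {(1, 2), (2, 3), (1, 3)}

    def test_boundary_of_boundary_vanishes(self):
        chain = Chain(2, frozenset({(1, 2, 3)}))
        assert chain.boundary().boundary().simplexes == frozenset()

    def test_dd_zero_on_all_complexes(self, small_graph_suite):
        for g in small_graph_suite:
            c = build_clique_complex(g)
            for q in range(2, c.bds + 1):
                dq = boundary_matrix(c, q)
                rows_lower = {s: i for i, s in enumerate(c.simplexes(q - 2))}
                for col, s in zip(dq.columns, dq.col_simplexes):
                    # apply d_{q-1} to the facet chain of s: must cancel
                    faces = [
                        dq.row_simplexes[i]
                        for i in range(len(dq.row_simplexes))
                        if col >> i & 1
                    ]
                    acc = 0
                    for f in faces:
                        for i in range(len(f)):
                            acc ^= 1 << rows_lower[f[:i] + f[i + 1 :]]
                    assert acc == 0

    def test_column_of_q_simplex_has_q_plus_1_ones(self):
        c = build_clique_complex(nx.complete_graph(5))
        for q in range(1, 5):
            for col in boundary_matrix(c, q).columns:
                assert bin(col).count("1") == q + 1


class TestBettiNumbers:
    @pytest.mark.parametrize(
        "graph,expected",
        [
            (nx.cycle_graph(4), [1, 1]),
            (nx.complete_graph(5), [1, 0, 0, 0, 0]),
            (nx.complete_multipartite_graph(2, 2, 2), [1, 0, 1]),  # hollow sphere
            (nx.path_graph(4), [1, 0]),
            (nx.empty_graph(3), [3]),
        ],
    )
    def test_known_complexes(self, graph, expected):
        assert betti_numbers(build_clique_complex(graph)).betti == expected

    def test_matches_dense_oracle(self, small_graph_suite):
        for g in small_graph_suite:
            got = betti_numbers(build_clique_complex(g)).betti
            assert got == dense_betti(g), f"mismatch on {sorted(g.edges)}"

    def test_betti0_equals_component_count(self, small_graph_suite):
        for g in small_graph_suite:
            if g.number_of_nodes() == 0:
                continue
            summary = betti_numbers(build_clique_complex(g))
            assert summary.betti[0] == nx.number_connected_components(g)

    def test_euler_characteristic_identity(self, small_graph_suite):
        for g in small_graph_suite:
            c = build_clique_complex(g)
            summary = betti_numbers(c)
            chi_simplexes = c.euler_characteristic()
            chi_betti = sum((-1) ** q * b for q, b in enumerate(summary.betti))
            assert chi_simplexes == chi_betti

    def test_disjoint_union_additivity(self):
        a, b = nx.cycle_graph(5), nx.complete_multipartite_graph(2, 2, 2)
        ba = betti_numbers(build_clique_complex(a)).betti
        bb = betti_numbers(build_clique_complex(b)).betti
        bu = betti_numbers(build_clique_complex(nx.disjoint_union(a, b))).betti
        width = max(len(ba), len(bb), len(bu))
        pad = lambda x: x + [0] * (width - len(x))
        assert pad(bu) == [x + y for x, y in zip(pad(ba), pad(bb))]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_graphs_match_oracle(self, seed):
        g = nx.erdos_renyi_graph(10, 0.4, seed=seed)
        assert betti_numbers(build_clique_complex(g)).betti == dense_betti(g)

    def test_bdc_reporting(self):
        ring = betti_numbers(build_clique_complex(nx.cycle_graph(4)))
        assert ring.bdc == 1
        solid = betti_numbers(build_clique_complex(nx.complete_graph(4)))
        assert solid.bdc == 0
        sphere = betti_numbers(build_clique_complex(nx.complete_multipartite_graph(2, 2, 2)))
        assert sphere.bdc == 2


class TestGenerators1:
    def test_unique_cycle_is_its_own_representative(self):
        c = build_clique_complex(nx.cycle_graph(6))
        gens = homology_generators_1(c)
        assert len(gens) == 1
        assert len(gens[0].chain) == 6

    def test_filled_triangles_give_no_generators(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        assert homology_generators_1(build_clique_complex(g)) == []

    def test_two_cavity_complex_minimal_representatives(self, fig_two_cavity_graph):
        """The cavity bordered by a filled triangle gets the 4-edge cycle
        through 3-4-7-5, not the homologous 5-edge detour through 6."""
        c = build_clique_complex(fig_two_cavity_graph)
        gens = homology_generators_1(c)
        node_sets = sorted(tuple(sorted(g.nodes)) for g in gens)
        assert node_sets == [(1, 2, 3, 4), (3, 4, 5, 7)]

    def test_variant_credits_detour_node(self, fig_two_cavity_graph):
        c = build_clique_complex(fig_two_cavity_graph)
        gens = homology_generators_1(c)
        by_nodes = {tuple(sorted(g.nodes)): g for g in gens}
        assert 6 in by_nodes[(3, 4, 5, 7)].nodes_on_any_variant

    def test_representatives_are_cycles_not_boundaries(self, small_graph_suite):
        for g in small_graph_suite:
            c = build_clique_complex(g)
            gens = homology_generators_1(c)
            assert len(gens) == betti_numbers(c).betti[1] if len(betti_numbers(c).betti) > 1 else not gens
            for rep in gens:
                assert rep.chain.boundary().simplexes == frozenset()
                assert not is_boundary(rep.chain, c)

    def test_representatives_mutually_independent(self, small_graph_suite):
        from ppitopo._gf2 import Gf2Basis
        from ppitopo.homology_gf2 import _edge_bitmask, _facets

        for g in small_graph_suite:
            c = build_clique_complex(g)
            gens = homology_generators_1(c)
            if not gens:
                continue
            idx = {e: i for i, e in enumerate(c.simplexes(1))}
            basis = Gf2Basis()
            for tri in c.simplexes(2):
                basis.add(_edge_bitmask(_facets(tri), idx))
            for rep in gens:
                assert basis.add(_edge_bitmask(rep.chain.simplexes, idx)), (
                    "representative dependent on boundaries and earlier classes"
                )


class TestIsBoundary:
    def test_triangle_boundary_detected(self):
        c = build_clique_complex(nx.complete_graph(3))
        chain = Chain(1, frozenset({(0, 1), (1, 2), (0, 2)}))
        assert is_boundary(chain, c)

    def test_hexagon_in_bare_cycle_is_not_boundary(self):
        c = build_clique_complex(nx.cycle_graph(6))
        chain = Chain(1, frozenset(c.simplexes(1)))
        assert not is_boundary(chain, c)

    def test_homologous_cycles_differ_by_boundary(self, fig_two_cavity_graph):
        c = build_clique_complex(fig_two_cavity_graph)
        short = Chain(1, frozenset({(3, 4), (4, 7), (5, 7), (3, 5)}))
        long = Chain(1, frozenset({(3, 4), (4, 7), (6, 7), (5, 6), (3, 5)}))
        assert is_boundary(short ^ long, c)

    def test_foreign_simplex_rejected(self):
        c = build_clique_complex(nx.cycle_graph(4))
        with pytest.raises(ValueError):
            is_boundary(Chain(1, frozenset({(10, 11)})), c)
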