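"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's bit-packed code paths:
clique enumeration is a brute-force scan over vertex subsets, and Betti
numbers come from dense numpy Gaussian elimination mod 2.
"""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest


def brute_force_cliques(graph: nx.Graph) -> dict[int, set[tuple]]:
    """All cliques of a small graph by scanning every vertex subset."""
    nodes = sorted(graph.nodes)
    assert len(nodes) <= 14, "oracle is exponential; keep fixtures small"
    out: dict[int, set[tuple]] = {}
    for size in range(1, len(nodes) + 1):
        for sub in combinations(nodes, size):
            if all(graph.has_edge(u, v) for u, v in combinations(sub, 2)):
                out.setdefault(size - 1, set()).add(tuple(sub))
    return out


def dense_gf2_rank(mat: np.ndarray) -> int:
    """Row-reduction rank over GF(2) on a dense 0/1 matrix."""
    a = mat.copy() % 2
    rank = 0
    rows, cols = a.shape
    for c in range(cols):
        pivot = None
        for r in range(rank, rows):
            if a[r, c]:
                pivot = r
                break
        if pivot is None:
            continue
        a[[rank, pivot]] = a[[pivot, rank]]
        for r in range(rows):
            if r != rank and a[r, c]:
                a[r] ^= a[rank]
        rank += 1
    return rank


def dense_betti(graph: nx.Graph, max_dim: int | None = None) -> list[int]:
    """Betti numbers of the flag complex via dense elimination (oracle)."""
    cliques = brute_force_cliques(graph)
    if not cliques:
        return []
    bds = max(cliques)
    top = bds if max_dim is None else min(max_dim, bds)
    simplexes = {d: sorted(cliques.get(d, ())) for d in range(top + 2)}
    ranks = {}
    for q in range(1, top + 2):
        rows, cols = simplexes[q - 1], simplexes[q]
        if not cols:
            ranks[q] = 0
            continue
        idx = {s: i for i, s in enumerate(rows)}
        mat = np.zeros((len(rows), len(cols)), dtype=np.uint8)
        for j, s in enumerate(cols):
            for i in range(len(s)):
                mat[idx[s[:i] + s[i + 1 :]], j] = 1
        ranks[q] = dense_gf2_rank(mat)
    return [
        len(simplexes[q]) - ranks.get(q, 0) - ranks.get(q + 1, 0) for q in range(top + 1)
    ]


@pytest.fixture(scope="session")
def small_graph_suite() -> list[nx.Graph]:
    """Assorted graphs on <= 12 nodes exercising varied topology."""
    graphs = [
        nx.empty_graph(3),
        nx.path_graph(5),
        nx.cycle_graph(4),
        nx.cycle_graph(6),
        nx.complete_graph(4),
        nx.complete_graph(5),
        nx.complete_multipartite_graph(2, 2, 2),  # octahedron: hollow sphere
        nx.star_graph(5),
        nx.wheel_graph(6),
        nx.petersen_graph(),
        nx.disjoint_union(nx.cycle_graph(4), nx.complete_graph(3)),
        nx.barbell_graph(4, 2),
    ]
    rng = np.random.default_rng(42)
    for n, p in [(8, 0.3), (10, 0.35), (12, 0.25), (12, 0.5), (9, 0.6)]:
        g = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(2**31)))
        graphs.append(g)
    return graphs


@pytest.fixture
def fig_two_cavity_graph() -> nx.Graph:
    """A square sharing a path with a pentagon whose chord triangle is
    filled: two 1-cavities, one of which has two homologous cycle shapes."""
    return nx.Graph(
        [(1, 2), (2, 3), (3, 4), (1, 4), (3, 5), (5, 7), (4, 7), (5, 6), (6, 7)]
    )
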