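"""Simplicial homology of a clique complex with GF(2) coefficients.

A q-chain is a set of q-simplexes (coefficient 1 = present) with
symmetric-difference addition.  The boundary map sends a q-simplex to the
sum of its (q-1)-faces; over GF(2) the orientation signs of the usual
alternating-sum formula vanish.  Betti numbers come from boundary-matrix
ranks:

    betti_q = n_q - rank(d_q) - rank(d_{q+1}),   rank(d_0) = 0,

so betti_0 counts connected components, betti_1 independent ring-shaped
cavities, betti_2 hollow-sphere cavities.  The largest dimension with a
non-zero Betti number (at dimension >= 1) is the biggest dimension of
cavity, BDC.

Dimension-1 homology classes additionally get explicit cycle
representatives: fundamental cycles of a spanning forest are reduced
against the triangle boundaries, one independent survivor per class, and
each representative is then shortened by swapping an arc for a graph
shortest path whenever the swap is verified homologous (the symmetric
difference with the original is a boundary).  The shortening is a greedy
fixed-point heuristic, not a guaranteed global minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ppitopo._gf2 import Gf2Basis, gf2_rank
from ppitopo.clique_complex import Simplex, SimplicialComplex

__all__ = [
    "Chain",
    "BoundaryMatrix",
    "HomologySummary",
    "CycleRepresentative",
    "boundary_matrix",
    "betti_numbers",
    "homology_generators_1",
    "is_boundary",
]


@dataclass(frozen=True)
class Chain:
    """A GF(2) chain: a set of same-dimension simplexes."""

    dimension: int
    simplexes: frozenset

    def __post_init__(self):
        for s in self.simplexes:
            if len(s) - 1 != self.dimension:
                raise ValueError(f"simplex {s} is not {self.dimension}-dimensional")

    def __xor__(self, other: "Chain") -> "Chain":
        if other.dimension != self.dimension:
            raise ValueError("chains of different dimension")
        return Chain(self.dimension, self.simplexes ^ other.simplexes)

    def __len__(self) -> int:
        return len(self.simplexes)

    def boundary(self) -> "Chain":
        """Sum of the facet boundaries of every member simplex."""
        if self.dimension == 0:
            # boundary of any 0-chain is zero; returned as an empty 0-chain
            return Chain(0, frozenset())
        faces: set = set()
        for s in self.simplexes:
            for i in range(len(s)):
                f = s[:i] + s[i + 1 :]
                faces.symmetric_difference_update({f})
        return Chain(self.dimension - 1, frozenset(faces))


@dataclass
class BoundaryMatrix:
    """Boundary map d_q as bitmask columns over the (q-1)-simplex basis."""

    dimension: int
    row_simplexes: list  # (q-1)-simplexes, sorted
    col_simplexes: list  # q-simplexes, sorted
    columns: list  # ints; bit i of column j set iff row i is a facet of col j

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_simplexes), len(self.col_simplexes))

    def rank(self) -> int:
        return gf2_rank(self.columns)


def _facets(s: Simplex):
    for i in range(len(s)):
        yield s[:i] + s[i + 1 :]


def boundary_matrix(complex_: SimplicialComplex, q: int) -> BoundaryMatrix:
    """The boundary map from q-chains to (q-1)-chains of the complex."""
    if q < 1:
        raise ValueError("boundary matrix defined for q >= 1")
    rows = complex_.simplexes(q - 1)
    cols = complex_.simplexes(q)
    row_index = {s: i for i, s in enumerate(rows)}
    columns = []
    for s in cols:
        col = 0
        for f in _facets(s):
            col |= 1 << row_index[f]
        columns.append(col)
    return BoundaryMatrix(dimension=q, row_simplexes=rows, col_simplexes=cols, columns=columns)


@dataclass
class CycleRepresentative:
    """One homology class: a minimal representative plus known variants.

    ``node_sequence`` traces the minimal representative as a closed walk;
    ``variants`` holds every homologous cycle met while shortening or
    expanding, each as a frozenset of edges -- these are what node
    cycle-involvement (q-DC) is counted against.
    """

    chain: Chain
    node_sequence: tuple
    variants: list[frozenset] = field(default_factory=list)

    @property
    def nodes(self) -> frozenset:
        return frozenset(v for e in self.chain.simplexes for v in e)

    @property
    def length(self) -> int:
        return len(self.chain)

    @property
    def nodes_on_any_variant(self) -> frozenset:
        out = set(self.nodes)
        for var in self.variants:
            out.update(v for e in var for v in e)
        return frozenset(out)


@dataclass
class HomologySummary:
    betti: list[int]
    bds: int
    generators_1: list[CycleRepresentative] | None = None

    @property
    def bdc(self) -> int:
        """Largest q >= 1 with betti_q > 0; 0 when no such cavity exists."""
        dims = [q for q, b in enumerate(self.betti) if b > 0 and q >= 1]
        return max(dims) if dims else 0


def betti_numbers(
    complex_: SimplicialComplex, max_dim: int | None = None
) -> HomologySummary:
    """Betti numbers up to ``max_dim`` (default: the complex's BDS)."""
    bds = complex_.bds
    if bds < 0:  # empty complex
        return HomologySummary(betti=[], bds=-1)
    top = bds if max_dim is None else min(max_dim, bds)
    ranks = {}  # q -> rank of d_q
    for q in range(1, top + 2):
        n_q = complex_.n_simplexes(q)
        ranks[q] = boundary_matrix(complex_, q).rank() if n_q else 0
    betti = []
    for q in range(top + 1):
        n_q = complex_.n_simplexes(q)
        b = n_q - ranks.get(q, 0) - ranks.get(q + 1, 0)
        betti.append(b)
    return HomologySummary(betti=betti, bds=bds)


def _edge_bitmask(edges, edge_index) -> int:
    m = 0
    for e in edges:
        m |= 1 << edge_index[e]
    return m


def _cycle_edges(seq) -> frozenset:
    """Edge set of the closed walk through ``seq`` (no repeated vertices)."""
    L = len(seq)
    return frozenset(tuple(sorted((seq[i], seq[(i + 1) % L]))) for i in range(L))


def _triangle_boundary_basis(complex_: SimplicialComplex, edge_index) -> Gf2Basis:
    basis = Gf2Basis()
    for tri in complex_.simplexes(2):
        basis.add(_edge_bitmask(_facets(tri), edge_index))
    return basis


def is_boundary(chain: Chain, complex_: SimplicialComplex) -> bool:
    """Whether ``chain`` lies in the image of the next boundary map."""
    q = chain.dimension
    basis_simplexes = set(complex_.simplexes_by_dim.get(q, ()))
    for s in chain.simplexes:
        if s not in basis_simplexes:
            raise ValueError(f"simplex {s} not in the complex")
    rows = complex_.simplexes(q)
    index = {s: i for i, s in enumerate(rows)}
    vec = _edge_bitmask(chain.simplexes, index)
    basis = Gf2Basis()
    for s in complex_.simplexes(q + 1):
        basis.add(_edge_bitmask(_facets(s), index))
    return basis.contains(vec)


def _graph_of(complex_: SimplicialComplex) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(v for (v,) in complex_.simplexes(0))
    g.add_edges_from(complex_.simplexes(1))
    return g


def _tighten(seq, graph, boundary_basis, edge_index):
    """Greedy arc-for-shortest-path exchange; returns (minimal seq, variants).

    Every accepted exchange must keep the cycle in the same homology
    class: the symmetric difference with the previous representative has
    to reduce to zero against the triangle-boundary basis.
    """
    variants: list[frozenset] = []
    improved = True
    while improved:
        improved = False
        L = len(seq)
        current_edges = _cycle_edges(seq)
        for i in range(L):
            if improved:
                break
            for j in range(i + 1, L):
                u, v = seq[i], seq[j]
                arc1 = seq[i : j + 1]  # u .. v forwards
                arc2 = seq[j:] + seq[: i + 1]  # v .. u wrapping
                try:
                    sp = nx.shortest_path(graph, u, v)
                except nx.NetworkXNoPath:  # pragma: no cover - same component
                    continue
                sp_inner = set(sp[1:-1])
                # replace either arc by the shortest path when it helps
                for kept, repl in ((arc1, arc2), (arc2[::-1], arc1[::-1])):
                    new_len = (len(kept) - 1) + (len(sp) - 1)
                    if new_len >= L or new_len < 3:
                        continue
                    if sp_inner & set(kept):
                        continue  # would pinch the cycle
                    cand_seq = tuple(kept[:-1]) + tuple(sp[::-1][:-1])
                    cand_edges = _cycle_edges(cand_seq)
                    if len(cand_edges) != new_len:
                        continue
                    diff = _edge_bitmask(current_edges ^ cand_edges, edge_index)
                    if boundary_basis.contains(diff):
                        variants.append(current_edges)
                        seq = cand_seq
                        improved = True
                        break
                if improved:
                    break
    # rotate/orient the sequence to a deterministic form
    mi = seq.index(min(seq))
    seq = seq[mi:] + seq[:mi]
    if len(seq) > 2 and seq[1] > seq[-1]:
        seq = (seq[0],) + seq[1:][::-1]
    return seq, variants


def _expand_variants(rep_edges: frozenset, complex_: SimplicialComplex, depth: int):
    """Homologous simple-cycle variants reached by adding triangle boundaries.

    Each round symmetric-differences the representative with the boundary
    of a triangle sharing an edge with it and keeps results that are
    again a single simple cycle.  Depth 1 suffices to credit every node
    that sits one filled triangle away from the minimal cycle.
    """
    out: list[frozenset] = []
    frontier = {rep_edges}
    seen = {rep_edges}
    for _ in range(depth):
        nxt = set()
        for cyc in frontier:
            for tri in complex_.simplexes(2):
                tb = frozenset(_facets(tri))
                if not (tb & cyc):
                    continue
                cand = cyc ^ tb
                if cand in seen or not cand:
                    continue
                if _is_single_simple_cycle(cand):
                    seen.add(cand)
                    nxt.add(cand)
        out.extend(nxt)
        frontier = nxt
    return out


def _is_single_simple_cycle(edges: frozenset) -> bool:
    deg: dict = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    if any(d != 2 for d in deg.values()):
        return False
    g = nx.Graph(list(edges))
    return nx.is_connected(g) and g.number_of_edges() == g.number_of_nodes()


def _fundamental_cycles(graph: nx.Graph):
    """Fundamental cycles of a BFS spanning forest, as vertex sequences."""
    out = []
    for component in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        sub = graph.subgraph(component)
        root = sorted(component)[0]
        parent = {root: None}
        for u, v in nx.bfs_edges(sub, root):
            parent[v] = u
        tree_edges = {tuple(sorted((u, v))) for v, u in parent.items() if u is not None}
        non_tree = sorted(
            tuple(sorted(e)) for e in sub.edges() if tuple(sorted(e)) not in tree_edges
        )
        for u, v in non_tree:

            def _path_to_root(x):
                p = [x]
                while parent[p[-1]] is not None:
                    p.append(parent[p[-1]])
                return p

            pu, pv = _path_to_root(u), _path_to_root(v)
            su = set(pu)
            lca = next(x for x in pv if x in su)
            out.append(tuple(pu[: pu.index(lca) + 1] + pv[: pv.index(lca)][::-1]))
    return out


def _shortest_cycle_candidates(graph: nx.Graph):
    """Per-edge shortest cycles: for every edge, the edge plus the shortest
    alternative path between its endpoints.  A pool of short simple cycles
    from which a near-minimal homology basis is drawn greedily."""
    out = []
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
        graph.remove_edge(u, v)
        try:
            sp = nx.shortest_path(graph, u, v)
            out.append(tuple(sp))
        except nx.NetworkXNoPath:
            pass
        finally:
            graph.add_edge(u, v)
    out.sort(key=lambda s: (len(s), s))
    return out


def homology_generators_1(
    complex_: SimplicialComplex, expand_depth: int = 1
) -> list[CycleRepresentative]:
    """One shortened cycle representative per dimension-1 homology class.

    Candidate simple cycles (each edge's shortest cycle, sorted by
    length, topped up with spanning-forest fundamental cycles) are
    reduced greedily against the triangle boundaries; each candidate
    that enlarges the span founds a new homology class, so short cycles
    claim classes first.  Each representative is then shortened to a
    locally minimal homologous simple cycle, and homologous variants
    (met during shortening, plus ``expand_depth`` rounds of
    triangle-boundary perturbations) are stored alongside it for
    cycle-involvement counting.
    """
    edges = complex_.simplexes(1)
    edge_index = {e: i for i, e in enumerate(edges)}
    graph = _graph_of(complex_)
    boundary_basis = _triangle_boundary_basis(complex_, edge_index)

    reps: list[CycleRepresentative] = []
    combined = Gf2Basis()
    for vec in boundary_basis.vectors():
        combined.add(vec)

    candidates = _shortest_cycle_candidates(graph) + _fundamental_cycles(graph)
    for seq in candidates:
        cyc_edges = _cycle_edges(seq)
        vec = _edge_bitmask(cyc_edges, edge_index)
        if not combined.add(vec):
            continue  # a boundary, or homologous to a class already found
        tight_seq, variants = _tighten(tuple(seq), graph, boundary_basis, edge_index)
        tight_edges = _cycle_edges(tight_seq)
        if tight_edges != cyc_edges:
            variants.append(cyc_edges)
        variants.extend(_expand_variants(tight_edges, complex_, expand_depth))
        variants = [v for v in dict.fromkeys(variants) if v != tight_edges]
        reps.append(
            CycleRepresentative(
                chain=Chain(1, frozenset(tight_edges)),
                node_sequence=tight_seq,
                variants=variants,
            )
        )
    return reps
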