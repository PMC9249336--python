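"""Clique (flag) complex of an undirected simple graph.

A q-simplex is a set of q+1 pairwise-connected vertices, so the simplexes
of the complex are exactly the cliques of the graph, and the maximal
simplexes are its maximal cliques.  The biggest dimension of any simplex
is abbreviated BDS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

__all__ = ["Simplex", "SimplicialComplex", "build_clique_complex", "maximal_simplexes", "simplex_census"]

#: A simplex: strictly increasing tuple of vertex labels.
Simplex = tuple

#: Above this dimension a dense region is probably a pathological input.
_DIM_WARN = 10


def _canon(vertices) -> Simplex:
    t = tuple(sorted(vertices))
    if len(set(t)) != len(t):
        raise ValueError(f"simplex has repeated vertices: {vertices}")
    return t


@dataclass
class SimplicialComplex:
    """Simplexes per dimension plus the maximal ones.

    Invariants: closed under faces; ``bds`` is the largest dimension with
    a non-empty simplex set; every maximal simplex is a face of no other.
    """

    simplexes_by_dim: dict[int, set[Simplex]] = field(default_factory=dict)
    maximal: set[Simplex] = field(default_factory=set)

    @property
    def bds(self) -> int:
        dims = [d for d, s in self.simplexes_by_dim.items() if s]
        return max(dims) if dims else -1

    def n_simplexes(self, dim: int) -> int:
        return len(self.simplexes_by_dim.get(dim, ()))

    def simplexes(self, dim: int) -> list[Simplex]:
        """Simplexes of one dimension in sorted order (stable indexing)."""
        return sorted(self.simplexes_by_dim.get(dim, ()))

    def has_simplex(self, vertices) -> bool:
        t = _canon(vertices)
        return t in self.simplexes_by_dim.get(len(t) - 1, ())

    @property
    def vertices(self) -> list:
        return [s[0] for s in self.simplexes(0)]

    def euler_characteristic(self) -> int:
        return sum(
            (-1) ** d * len(s) for d, s in self.simplexes_by_dim.items()
        )


def build_clique_complex(net: nx.Graph, max_dim: int | None = None) -> SimplicialComplex:
    """Build the flag complex of ``net``.

    The q-simplexes are exactly the (q+1)-cliques; isolated nodes are
    0-simplexes.  ``max_dim`` caps enumeration (faces up to that
    dimension are still complete, so homology below the cap is exact).
    """
    if max_dim is not None and max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    by_dim: dict[int, set[Simplex]] = {0: {(v,) for v in net.nodes}}
    maximal_cliques = [tuple(sorted(c)) for c in nx.find_cliques(net)] if net.number_of_nodes() else []
    for clique in maximal_cliques:
        dim = len(clique) - 1
        if max_dim is None and dim > _DIM_WARN:
            warnings.warn(
                f"clique of {len(clique)} vertices found; the flag complex may be huge "
                f"(consider max_dim)"
            )
        top = dim if max_dim is None else min(dim, max_dim)
        for q in range(1, top + 1):
            bucket = by_dim.setdefault(q, set())
            for face in combinations(clique, q + 1):
                bucket.add(face)
    maximal = {c for c in maximal_cliques}
    return SimplicialComplex(simplexes_by_dim=by_dim, maximal=maximal)


def maximal_simplexes(complex_: SimplicialComplex) -> set[Simplex]:
    """The simplexes that are faces of no other simplex."""
    return set(complex_.maximal)


def simplex_census(complex_: SimplicialComplex) -> pd.DataFrame:
    """Per-dimension counts of simplexes and maximal simplexes."""
    max_by_dim: dict[int, int] = {}
    for s in complex_.maximal:
        d = len(s) - 1
        max_by_dim[d] = max_by_dim.get(d, 0) + 1
    rows = []
    for d in sorted(complex_.simplexes_by_dim):
        n = complex_.n_simplexes(d)
        if n:
            rows.append(
                {"dimension": d, "n_simplexes": n, "n_maximal": max_by_dim.get(d, 0)}
            )
    df = pd.DataFrame(rows, columns=["dimension", "n_simplexes", "n_maximal"])
    df.attrs["bds"] = complex_.bds
    return df


def census_json(complex_: SimplicialComplex) -> str:
    df = simplex_census(complex_)
    return json.dumps(
        {"bds": complex_.bds, "census": df.to_dict(orient="records")}, indent=2
    )
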