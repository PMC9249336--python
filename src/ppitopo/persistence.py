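"""Edge filtrations, Betti curves and persistence intervals.

A filtration is a nested sequence of complexes built by introducing
simplexes at non-decreasing values.  For a weighted interaction network
the natural filtration adds edges in order of reliability (weight), each
edge dragging in every higher clique it completes, so the complex at each
step is the flag complex of the edges added so far.  Explicitly listed
filtrations (value -> simplexes) are supported too, for worked examples
that place triangles at chosen values.

Persistence pairs births and deaths of homology classes by the standard
GF(2) column reduction of the filtered boundary matrix; classes still
alive at the end of the filtration get an open (infinite) death.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from ppitopo._gf2 import Gf2Basis
from ppitopo.clique_complex import Simplex, SimplicialComplex
from ppitopo.homology_gf2 import betti_numbers

__all__ = [
    "FiltrationStep",
    "Filtration",
    "PersistenceInterval",
    "filtration_from_weights",
    "filtration_from_table",
    "betti_curve",
    "persistence_intervals",
]


@dataclass
class FiltrationStep:
    value: float
    simplexes: list  # canonical simplexes introduced at this value


@dataclass
class Filtration:
    """Ordered filtration steps with face-before-coface validation."""

    steps: list[FiltrationStep] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Check monotone values and uniqueness; complete missing faces.

        A simplex listed without one of its faces (worked examples often
        leave the enabling edge implicit) gets the face inserted at the
        same step, ahead of it.
        """
        seen: set = set()
        last = -math.inf
        for step in self.steps:
            if step.value < last:
                raise ValueError("filtration values must be non-decreasing")
            last = step.value
            completed: list = []
            for s in sorted(step.simplexes, key=lambda t: (len(t), t)):
                if s in seen:
                    raise ValueError(f"simplex {s} introduced twice")
                for size in range(1, len(s)):
                    for f in combinations(s, size):
                        if f not in seen:
                            completed.append(f)
                            seen.add(f)
                completed.append(s)
                seen.add(s)
            step.simplexes = completed

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def accumulated_complex(self, upto: int | None = None) -> SimplicialComplex:
        """Complex formed by all simplexes of the first ``upto`` steps."""
        by_dim: dict[int, set] = {}
        for step in self.steps[: upto if upto is not None else len(self.steps)]:
            for s in step.simplexes:
                by_dim.setdefault(len(s) - 1, set()).add(s)
        return SimplicialComplex(simplexes_by_dim=by_dim)


@dataclass(frozen=True)
class PersistenceInterval:
    dimension: int
    birth: float
    death: float  # math.inf when the class survives the filtration

    @property
    def lifetime(self) -> float:
        return self.death - self.birth


def _new_cliques_for_edge(graph: nx.Graph, u, v) -> list[Simplex]:
    """All cliques through edge (u, v) in ``graph`` (edge already added)."""
    common = sorted(set(graph[u]) & set(graph[v]))
    out: list[Simplex] = [tuple(sorted((u, v)))]
    if common:
        sub = graph.subgraph(common)
        for c in nx.enumerate_all_cliques(sub):
            out.append(tuple(sorted((u, v) + tuple(c))))
    return out


def filtration_from_weights(net: nx.Graph, order: str = "descending") -> Filtration:
    """Flag filtration of a weighted network, one edge per step.

    Edges enter by weight rank -- descending by default, since a larger
    weight marks a more reliable interaction -- with ties broken by input
    order.  Each step introduces the edge plus every clique it completes;
    all vertices enter at a step preceding the first edge.
    """
    if order not in ("descending", "ascending"):
        raise ValueError("order must be 'descending' or 'ascending'")
    edges = list(net.edges(data=True))
    missing = [e for e in edges if "weight" not in e[2]]
    if missing:
        warnings.warn("some edges lack weights; keeping input order")
        ordered = edges
    else:
        reverse = order == "descending"
        ordered = sorted(
            enumerate(edges), key=lambda t: (-t[1][2]["weight"] if reverse else t[1][2]["weight"], t[0])
        )
        ordered = [e for _, e in ordered]
    steps: list[FiltrationStep] = []
    first_value = ordered[0][2].get("weight", 0.0) if ordered else 0.0
    steps.append(FiltrationStep(value=float(first_value), simplexes=[(v,) for v in sorted(net.nodes)]))
    accum = nx.Graph()
    accum.add_nodes_from(net.nodes)
    for u, v, data in ordered:
        accum.add_edge(u, v)
        steps.append(
            FiltrationStep(
                value=float(data.get("weight", 0.0)),
                simplexes=_new_cliques_for_edge(accum, u, v),
            )
        )
    # descending weights give decreasing step values; re-index to ranks so
    # the filtration parameter is monotone while the weight stays reported
    if order == "descending" and len(steps) > 1:
        for rank, step in enumerate(steps):
            step.value = float(rank)
    return Filtration(steps=steps)


def filtration_from_table(df: pd.DataFrame) -> Filtration:
    """Explicit filtration from rows of (value, space-separated vertices)."""
    steps: dict[float, list] = {}
    for _, row in df.iterrows():
        val = float(row["value"])
        verts = tuple(sorted(str(row["simplex"]).split()))
        steps.setdefault(val, []).append(verts)
    return Filtration(
        steps=[FiltrationStep(value=v, simplexes=s) for v, s in sorted(steps.items())]
    )


def betti_curve(filtration: Filtration, max_dim: int = 2) -> pd.DataFrame:
    """Betti numbers of the accumulated complex after every step.

    Returns one row per step: step index, filtration value, cumulative
    count of edges added, and betti_0..betti_{max_dim} computed from
    scratch on the accumulated complex.
    """
    rows = []
    edges_added = 0
    by_dim: dict[int, set] = {}
    for i, step in enumerate(filtration.steps):
        for s in step.simplexes:
            by_dim.setdefault(len(s) - 1, set()).add(s)
        edges_added = len(by_dim.get(1, ()))
        complex_ = SimplicialComplex(simplexes_by_dim={d: set(v) for d, v in by_dim.items()})
        summary = betti_numbers(complex_, max_dim=max_dim)
        betti = summary.betti + [0] * (max_dim + 1 - len(summary.betti))
        rows.append(
            {"step": i, "value": step.value, "edges_added": edges_added}
            | {f"betti_{q}": betti[q] for q in range(max_dim + 1)}
        )
    return pd.DataFrame(rows)


def persistence_intervals(
    filtration: Filtration, q: int, include_zero: bool = False
) -> list[PersistenceInterval]:
    """Birth/death intervals of dimension-q classes.

    Standard persistence pairing: simplexes enter in filtration order
    (faces first within a step); each boundary column is reduced over
    GF(2) against earlier columns sharing its pivot.  A column that
    reduces to zero creates a class; a surviving column kills the class
    created by its pivot simplex.  Classes born and killed at the same
    filtration value never exist at any value and are dropped unless
    ``include_zero`` is set.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    order: list[tuple[Simplex, float]] = []
    for step in filtration.steps:
        for s in sorted(step.simplexes, key=lambda t: (len(t), t)):
            order.append((s, step.value))
    index = {s: i for i, (s, _) in enumerate(order)}
    values = [v for _, v in order]

    low_to_col: dict[int, int] = {}
    reduced: dict[int, int] = {}
    creator: dict[int, bool] = {}
    pairs: list[tuple[int, int]] = []
    for j, (s, _) in enumerate(order):
        if len(s) == 1:
            creator[j] = True
            continue
        col = 0
        for i in range(len(s)):
            f = s[:i] + s[i + 1 :]
            col |= 1 << index[f]
        while col:
            low = col.bit_length() - 1
            other = low_to_col.get(low)
            if other is None:
                break
            col ^= reduced[other]
        if col:
            low = col.bit_length() - 1
            low_to_col[low] = j
            reduced[j] = col
            creator[j] = False
            pairs.append((low, j))
        else:
            creator[j] = True

    killed = {b for b, _ in pairs}
    intervals: list[PersistenceInterval] = []
    for b, d in pairs:
        if len(order[b][0]) - 1 == q and (include_zero or values[d] > values[b]):
            intervals.append(
                PersistenceInterval(dimension=q, birth=values[b], death=values[d])
            )
    for j, (s, _) in enumerate(order):
        if creator.get(j) and len(s) - 1 == q and j not in killed:
            intervals.append(
                PersistenceInterval(dimension=q, birth=values[j], death=math.inf)
            )
    intervals.sort(key=lambda iv: (iv.birth, iv.death))
    return intervals


def intervals_table(intervals: list[PersistenceInterval]) -> pd.DataFrame:
    rows = [
        {
            "dim": iv.dimension,
            "birth": iv.birth,
            "death": iv.death if math.isfinite(iv.death) else "inf",
            "lifetime": iv.lifetime if math.isfinite(iv.death) else "inf",
        }
        for iv in intervals
    ]
    return pd.DataFrame(rows, columns=["dim", "birth", "death", "lifetime"])
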