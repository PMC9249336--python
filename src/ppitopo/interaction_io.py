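"""Reading, writing and combining protein-interaction edge lists.

Interaction datasets arrive as tab-separated files with two identifier
columns and an optional weight column.  Pairs are canonicalized to an
unordered form (lexicographically sorted endpoints), self-interactions are
rejected, and overlaps across datasets are tallied so that a combined
network can be assembled from the interactions seen in at least *k*
sources.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: An interaction pair: a 2-tuple of protein identifiers, endpoints sorted.
Pair = tuple[str, str]


class SelfInteractionError(ValueError):
    """A pair whose two endpoints are the same protein."""


def canonicalize_pair(a: str, b: str) -> Pair:
    """Return the canonical unordered form of an interaction pair.

    Identifiers are whitespace-trimmed and compared case-sensitively; the
    returned tuple has its endpoints in lexicographic order.

    Raises
    ------
    ValueError
        If either identifier is empty after trimming.
    SelfInteractionError
        If both identifiers coincide (self-interactions carry no
        information for the simplicial machinery, which assumes distinct
        vertices).
    """
    a = str(a).strip()
    b = str(b).strip()
    if not a or not b:
        raise ValueError("protein identifiers must be non-empty")
    if a == b:
        raise SelfInteractionError(f"self-interaction rejected: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class InteractionSet:
    """A named collection of canonical unordered protein pairs."""

    name: str
    pairs: set[Pair] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.pairs)

    @property
    def proteins(self) -> set[str]:
        return {p for pair in self.pairs for p in pair}

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.pairs


@dataclass
class OverlapTally:
    """Cross-dataset multiplicity of every interaction pair.

    ``multiplicity[pair]`` is the number of datasets containing the pair;
    ``counts_at_least[k]`` is the number of distinct pairs present in at
    least *k* datasets (non-increasing in *k*).
    """

    multiplicity: dict[Pair, int]
    n_sets: int

    @property
    def counts_at_least(self) -> dict[int, int]:
        out = {}
        for k in range(1, self.n_sets + 1):
            out[k] = sum(1 for m in self.multiplicity.values() if m >= k)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_sets": self.n_sets,
                "n_distinct_pairs": len(self.multiplicity),
                "counts_at_least": self.counts_at_least,
            },
            indent=2,
        )


def load_interaction_table(
    path: str | Path,
    id_cols: tuple[str, str] = ("protein_a", "protein_b"),
    weight_col: str | None = None,
    name: str | None = None,
) -> InteractionSet:
    """Load a TSV edge list into an :class:`InteractionSet`.

    Duplicate rows (after canonicalization) collapse to one pair;
    self-interactions are dropped and their count logged.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    id_cols:
        Names of the two identifier columns.
    weight_col:
        Optional weight column; currently ignored for set membership but
        validated to exist when given.
    name:
        Dataset label; defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in id_cols:
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path} (has {list(df.columns)})")
    if weight_col is not None and weight_col not in df.columns:
        raise ValueError(f"weight column {weight_col!r} missing from {path}")
    pairs: set[Pair] = set()
    n_self = 0
    for a, b in zip(df[id_cols[0]], df[id_cols[1]]):
        try:
            pairs.add(canonicalize_pair(a, b))
        except SelfInteractionError:
            n_self += 1
    if n_self:
        logger.warning("%s: dropped %d self-interaction(s)", path.name, n_self)
    if not pairs:
        logger.warning("%s: no interactions loaded", path.name)
    iset = InteractionSet(name=name or path.stem, pairs=pairs)
    logger.info("%s: %d canonical pairs", iset.name, iset.size)
    return iset


def write_interaction_table(iset: InteractionSet, path: str | Path) -> None:
    """Write an interaction set as a canonical sorted TSV edge list."""
    df = pd.DataFrame(sorted(iset.pairs), columns=["protein_a", "protein_b"])
    df.to_csv(path, sep="\t", index=False)


def count_overlaps(sets: Iterable[InteractionSet]) -> OverlapTally:
    """Tally, for every pair, in how many datasets it occurs."""
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least two interaction sets to count overlaps")
    multiplicity: dict[Pair, int] = {}
    for iset in sets:
        for pair in iset.pairs:
            multiplicity[pair] = multiplicity.get(pair, 0) + 1
    return OverlapTally(multiplicity=multiplicity, n_sets=len(sets))


def build_combined_network(tally: OverlapTally, min_multiplicity: int = 2) -> nx.Graph:
    """Assemble the combined network from sufficiently overlapped pairs.

    Edges are exactly the pairs with multiplicity >= ``min_multiplicity``;
    nodes are the endpoints of those edges (proteins whose every
    interaction fell below the threshold are not carried over).  Each
    edge's ``weight`` attribute is its overlap multiplicity, which serves
    as the default reliability score for downstream filtrations.
    """
    if min_multiplicity < 1:
        raise ValueError("min_multiplicity must be >= 1")
    g = nx.Graph()
    for pair, m in tally.multiplicity.items():
        if m >= min_multiplicity:
            g.add_edge(pair[0], pair[1], weight=m)
    if g.number_of_edges() == 0:
        logger.warning("no interaction reached multiplicity >= %d", min_multiplicity)
    return g


def network_from_pairs(pairs: Iterable[Pair], weights: Mapping[Pair, float] | None = None) -> nx.Graph:
    """Build a simple undirected graph from canonical pairs."""
    g = nx.Graph()
    for pair in pairs:
        w = weights.get(pair) if weights else None
        if w is None:
            g.add_edge(*pair)
        else:
            g.add_edge(*pair, weight=w)
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    """Write a network as a TSV edge list with a weight column when present."""
    rows = []
    for u, v, data in g.edges(data=True):
        a, b = (u, v) if str(u) < str(v) else (v, u)
        rows.append({"protein_a": a, "protein_b": b, "weight": data.get("weight", "")})
    pd.DataFrame(sorted(rows, key=lambda r: (r["protein_a"], r["protein_b"]))).to_csv(
        path, sep="\t", index=False
    )


def load_network(
    path: str | Path,
    id_cols: tuple[str, str] = ("protein_a", "protein_b"),
    weight_col: str | None = "weight",
) -> nx.Graph:
    """Load a TSV edge list into a simple undirected graph."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    has_w = weight_col is not None and weight_col in df.columns
    for _, row in df.iterrows():
        try:
            a, b = canonicalize_pair(str(row[id_cols[0]]), str(row[id_cols[1]]))
        except SelfInteractionError:
            continue
        if has_w and pd.notna(row[weight_col]) and str(row[weight_col]) != "":
            g.add_edge(a, b, weight=float(row[weight_col]))
        else:
            g.add_edge(a, b)
    return g
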