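"""Seeded generators emulating the study's inputs.

Three generators cover the pipeline's input space:

* ``gen_overlap_datasets`` -- several interaction datasets sampled
  independently from a shared universe of protein pairs, with a planted
  set of true interactions that each dataset picks up with a given
  probability; the remainder of each dataset is uniform background.
  With no planting the overlap counts follow the random-overlap null.
* ``gen_planted_cavity_graph`` -- a graph with a known homology:
  chordless cycles of length >= 4 each contribute one 1-cavity,
  octahedra (the smallest flag-complex hollow sphere) each contribute
  one 2-cavity, and random trees contribute nothing; components are
  optionally joined by bridge (cut) edges, which create no new cycles,
  so the expected Betti numbers follow by additivity.
* ``gen_powerlaw_degree_sequence`` -- heavy-tailed degree sequences such
  as interaction networks exhibit, repaired to graphicality.

Every generator is exactly reproducible from its parameters plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from ppitopo.interaction_io import InteractionSet, Pair

__all__ = [
    "OverlapScenario",
    "PlantedTopology",
    "gen_overlap_datasets",
    "gen_planted_cavity_graph",
    "gen_powerlaw_degree_sequence",
]


@dataclass(frozen=True)
class OverlapScenario:
    """Shared-universe sampling design for several interaction datasets."""

    n_proteins: int
    subset_sizes: tuple[int, ...]
    n_true: int = 0
    detect_prob: float = 1.0
    seed: int = 0

    @property
    def universe_size(self) -> int:
        return self.n_proteins * (self.n_proteins - 1) // 2

    def __post_init__(self):
        if self.n_proteins < 2:
            raise ValueError("need at least two proteins")
        for n in self.subset_sizes:
            if not (0 < n <= self.universe_size):
                raise ValueError(f"subset size {n} infeasible for universe {self.universe_size}")
        if not (0 <= self.n_true <= min(self.subset_sizes, default=0)):
            raise ValueError("planted true-pair count must fit in every subset")
        if not (0.0 <= self.detect_prob <= 1.0):
            raise ValueError("detect_prob must be a probability")


@dataclass(frozen=True)
class PlantedTopology:
    """Planted cavity counts for a ground-truth homology graph."""

    n_1cavities: int = 0
    n_2cavities: int = 0
    cycle_length: int = 4
    tree_size: int = 0
    bridged: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_1cavities < 0 or self.n_2cavities < 0:
            raise ValueError("planted counts must be >= 0")
        if self.cycle_length < 4:
            raise ValueError("chordless planted cycles need length >= 4")


def _pair_from_index(idx: int, n: int) -> Pair:
    i = int((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * idx)) // 2)
    j = int(idx - i * (2 * n - i - 1) // 2 + i + 1)
    return (f"p{i:04d}", f"p{j:04d}")


def gen_overlap_datasets(
    scenario: OverlapScenario,
) -> tuple[list[InteractionSet], set[Pair]]:
    """Sample interaction datasets from a shared pair universe.

    Returns the datasets plus the planted ground-truth pair set.  Each
    dataset keeps every true pair independently with ``detect_prob`` and
    fills up to its nominal size with uniformly chosen background pairs,
    so a dataset's size is exact and its non-planted content is a
    uniform draw -- the null of the random-overlap model.
    """
    rng = np.random.default_rng(scenario.seed)
    U = scenario.universe_size
    true_idx = rng.choice(U, size=scenario.n_true, replace=False) if scenario.n_true else np.array([], dtype=int)
    true_pairs = {_pair_from_index(int(i), scenario.n_proteins) for i in true_idx}
    datasets = []
    for d, size in enumerate(scenario.subset_sizes):
        kept = [int(i) for i in true_idx if rng.random() < scenario.detect_prob]
        kept_set = set(kept)
        n_fill = size - len(kept)
        fill: list[int] = []
        while len(fill) < n_fill:
            cand = rng.choice(U, size=n_fill - len(fill) + 8, replace=False)
            for c in cand:
                c = int(c)
                if c not in kept_set:
                    fill.append(c)
                    kept_set.add(c)
                if len(fill) == n_fill:
                    break
        pairs = {_pair_from_index(i, scenario.n_proteins) for i in kept + fill}
        datasets.append(InteractionSet(name=f"dataset_{d}", pairs=pairs))
    return datasets, true_pairs


def _octahedron(label: str) -> nx.Graph:
    """K(2,2,2): the minimal flag complex homeomorphic to a hollow sphere."""
    g = nx.Graph()
    nodes = [f"{label}_{i}" for i in range(6)]
    opposite = {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4}
    for i, j in combinations(range(6), 2):
        if opposite[i] != j:
            g.add_edge(nodes[i], nodes[j])
    return g


def gen_planted_cavity_graph(
    spec: PlantedTopology,
) -> tuple[nx.Graph, tuple[int, int, int]]:
    """A graph with known Betti numbers (betti_0, betti_1, betti_2).

    Components: ``n_1cavities`` chordless cycles, ``n_2cavities``
    octahedra, and one random tree of ``tree_size`` nodes when
    requested.  With ``bridged=True`` the components are chained by
    single bridge edges between randomly chosen endpoints; bridges are
    cut edges and change only betti_0.
    """
    rng = np.random.default_rng(spec.seed)
    parts: list[nx.Graph] = []
    for c in range(spec.n_1cavities):
        parts.append(nx.cycle_graph([f"c{c}_{i}" for i in range(spec.cycle_length)]))
    for o in range(spec.n_2cavities):
        parts.append(_octahedron(f"o{o}"))
    if spec.tree_size > 0:
        tree = nx.random_labeled_tree(spec.tree_size, seed=int(rng.integers(2**31)))
        parts.append(nx.relabel_nodes(tree, {i: f"t_{i}" for i in tree.nodes}))
    if not parts:
        g = nx.Graph()
        return g, (0, 0, 0)
    g = nx.union_all(parts)
    if spec.bridged and len(parts) > 1:
        for a, b in zip(parts[:-1], parts[1:]):
            u = sorted(a.nodes)[int(rng.integers(len(a)))]
            v = sorted(b.nodes)[int(rng.integers(len(b)))]
            g.add_edge(u, v)
    b0 = 1 if spec.bridged else len(parts)
    b1 = spec.n_1cavities
    b2 = spec.n_2cavities
    return g, (b0, b1, b2)


def gen_powerlaw_degree_sequence(
    n: int, exponent: float = 2.5, seed: int = 0, d_min: int = 1
) -> list[int]:
    """A graphical degree sequence with power-law tail.

    Degrees are drawn from the discrete distribution P(d) ~ d^-exponent
    on [d_min, n-1], the sum is made even by decrementing one odd entry,
    and the largest degrees are decremented until the Erdos-Gallai
    condition holds.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if exponent <= 1:
        raise ValueError("exponent must exceed 1")
    rng = np.random.default_rng(seed)
    support = np.arange(d_min, n)
    probs = support.astype(float) ** -exponent
    probs /= probs.sum()
    seq = list(int(d) for d in rng.choice(support, size=n, p=probs))
    if sum(seq) % 2:
        # decrement a largest entry (stays >= d_min - 1 >= 0)
        i = int(np.argmax(seq))
        seq[i] -= 1
    while not nx.is_graphical(sorted(seq, reverse=True), method="eg"):
        i = int(np.argmax(seq))
        seq[i] -= 2 if (seq[i] >= 2) else 0
        if seq[i] < 0:  # pragma: no cover - defensive
            seq[i] = 0
    return seq
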