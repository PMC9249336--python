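"""Null-model network ensembles for topological comparison.

Two controls: ``random_net`` holds the node and edge counts fixed (a
uniform G(n, m) draw, equivalent to adding uniformly chosen new edges one
at a time until the target count is reached) and ``random_net_same_dd``
holds the entire degree sequence fixed, realizing it by a randomized
Havel-Hakimi-style construction that adds one edge at a time while
keeping the residual sequence graphical.  ``ensemble_stats`` summarizes
any scalar network statistic over repeated draws with mean, sample SD and
a normal-approximation 95% CI (mean +/- 1.96 SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from ppitopo.clique_complex import build_clique_complex
from ppitopo.homology_gf2 import betti_numbers

__all__ = [
    "GraphicalityError",
    "EnsembleStats",
    "random_net",
    "random_net_same_dd",
    "ensemble_stats",
    "topology_statistics",
]


class GraphicalityError(ValueError):
    """A degree sequence that no simple graph can realize."""


@dataclass
class EnsembleStats:
    statistic: str
    n_samples: int
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    samples: list[float] | None = None

    @classmethod
    def from_samples(cls, name: str, values: Sequence[float], keep_samples: bool = True):
        """Mean, sample SD (ddof=1) and the mean +/- 1.96 SD interval."""
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least two samples")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        return cls(
            statistic=name,
            n_samples=arr.size,
            mean=mean,
            sd=sd,
            ci_lower=mean - 1.96 * sd,
            ci_upper=mean + 1.96 * sd,
            samples=list(map(float, arr)) if keep_samples else None,
        )


def random_net(n_nodes: int, n_edges: int, seed: int | np.random.Generator) -> nx.Graph:
    """Uniform simple graph with exactly ``n_nodes`` nodes and ``n_edges`` edges.

    Chooses ``n_edges`` distinct pairs uniformly from all possible pairs,
    which is the stationary outcome of adding one uniformly random new
    edge per step until the target count is reached.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ValueError(f"n_edges={n_edges} outside [0, {max_edges}] for n={n_nodes}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for idx in chosen:
        # unrank pair index into (i, j), i < j
        i = int((2 * n_nodes - 1 - math.sqrt((2 * n_nodes - 1) ** 2 - 8 * idx)) // 2)
        j = int(idx - i * (2 * n_nodes - i - 1) // 2 + i + 1)
        g.add_edge(i, j)
    assert g.number_of_edges() == n_edges
    return g


def _is_graphical(seq: Sequence[int]) -> bool:
    if any(d < 0 for d in seq):
        return False
    if sum(seq) % 2:
        return False
    return nx.is_graphical(sorted(seq, reverse=True), method="eg")


def random_net_same_dd(
    seq: Sequence[int], seed: int | np.random.Generator, max_restarts: int = 100
) -> nx.Graph:
    """Random simple graph whose degree sequence equals ``seq`` exactly.

    Randomized constructive realization, one edge per step: a node of
    minimal positive residual degree (random among ties) is saturated by
    connecting it to randomly ordered admissible partners, accepting an
    edge only if the residual sequence remains graphical (Erdos-Gallai
    check) -- the randomized converse of the Havel-Hakimi reduction.
    Saturating the minimal-degree node before moving on guarantees an
    admissible partner always exists, so the restart cap is a safety net
    only.
    """
    seq = list(int(d) for d in seq)
    if not _is_graphical(seq):
        if sum(seq) % 2:
            raise GraphicalityError(f"degree sum {sum(seq)} is odd")
        raise GraphicalityError(f"sequence {seq} violates the Erdos-Gallai condition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(seq)
    for _attempt in range(max_restarts):
        residual = list(seq)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        dead = False
        while any(residual) and not dead:
            mind = min(d for d in residual if d > 0)
            v = int(rng.choice([u for u in range(n) if residual[u] == mind]))
            while residual[v] > 0 and not dead:
                partners = [
                    u
                    for u in range(n)
                    if u != v and residual[u] > 0 and not g.has_edge(u, v)
                ]
                rng.shuffle(partners)
                placed = False
                for u in partners:
                    residual[v] -= 1
                    residual[u] -= 1
                    if _is_graphical(residual):
                        g.add_edge(v, u)
                        placed = True
                        break
                    residual[v] += 1
                    residual[u] += 1
                if not placed:
                    dead = True
        if not dead:
            assert sorted(d for _, d in g.degree()) == sorted(seq)
            return g
    raise RuntimeError(f"failed to realize degree sequence after {max_restarts} restarts")


def topology_statistics(g: nx.Graph, max_dim: int = 2) -> dict[str, float]:
    """Betti numbers, BDS and BDC of the flag complex of ``g``."""
    complex_ = build_clique_complex(g, max_dim=max_dim + 1)
    summary = betti_numbers(complex_, max_dim=max_dim)
    betti = summary.betti + [0] * (max_dim + 1 - len(summary.betti))
    out = {f"betti{q}": float(betti[q]) for q in range(max_dim + 1)}
    # BDS from maximal cliques (exact even when simplex enumeration is capped)
    bds = max((len(c) - 1 for c in nx.find_cliques(g)), default=0) if g.number_of_nodes() else -1
    out["bds"] = float(bds)
    out["bdc"] = float(summary.bdc)
    return out


def ensemble_stats(
    generator: Callable[[np.random.Generator], nx.Graph],
    n_samples: int,
    statistic: str | Callable[[nx.Graph], float],
    seed: int,
    max_dim: int = 2,
) -> EnsembleStats:
    """Summarize a statistic over ``n_samples`` draws of a null model.

    ``statistic`` is either a callable ``graph -> float`` or one of the
    named topological statistics ``betti0/betti1/betti2/bds/bdc``.
    Per-sample values are retained on the result for audit.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "statistic")
    values = []
    for _ in range(n_samples):
        g = generator(rng)
        if callable(statistic):
            values.append(float(statistic(g)))
        else:
            values.append(topology_statistics(g, max_dim=max_dim)[statistic])
    return EnsembleStats.from_samples(name, values)
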