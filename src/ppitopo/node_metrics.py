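"""Per-node network metrics, classical and homological.

Classical metrics follow the usual conventions for undirected simple
graphs: degree; local clustering (edges among neighbors over the
possible ones); betweenness with fractional credit across co-minimal
geodesics, endpoints excluded, normalized by (N-1)(N-2)/2; harmonic
closeness (sum of reciprocal distances over N-1, unreachable pairs
contributing 0); and a per-node "assortativity" -- the Pearson
correlation, over all other nodes u, between the reciprocal distance
1/d(v, u) and a target metric of u (degree, closeness or betweenness).

The homological metric q-DC counts, for each node, the number of
q-dimensional homology classes (cavities) whose stored cycle
representatives pass through the node -- a global involvement measure
that can be high for nodes of low degree.  Cycles themselves are ranked
by the mean q-DC of their member nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ppitopo.clique_complex import build_clique_complex
from ppitopo.homology_gf2 import CycleRepresentative, homology_generators_1

__all__ = [
    "degree",
    "clustering",
    "betweenness",
    "closeness",
    "assortativity",
    "q_dc",
    "rank_cycles",
    "RankedCycle",
    "node_metric_table",
]


def degree(net: nx.Graph) -> dict:
    """Number of neighbors of each node."""
    return dict(net.degree())


def clustering(net: nx.Graph) -> dict:
    """Local clustering coefficient 2 e_i / (k_i (k_i - 1)); 0 below degree 2."""
    return {v: float(c) for v, c in nx.clustering(net).items()}


def betweenness(net: nx.Graph) -> dict:
    """Share of shortest paths passing through each node.

    Fractional credit over equally short paths, endpoints excluded,
    normalized by (N-1)(N-2)/2 so values lie in [0, 1].  Graphs with
    fewer than 3 nodes have no inner vertices; all zeros.
    """
    n = net.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in net.nodes}
    return {v: float(b) for v, b in nx.betweenness_centrality(net, normalized=True).items()}


def closeness(net: nx.Graph) -> dict:
    """Harmonic closeness: (sum over u of 1/d(v, u)) / (N - 1).

    Reciprocal distances keep disconnected pairs finite (1/inf = 0).
    """
    n = net.number_of_nodes()
    if n <= 1:
        return {v: 0.0 for v in net.nodes}
    hc = nx.harmonic_centrality(net)
    return {v: float(h) / (n - 1) for v, h in hc.items()}


def _reciprocal_distance_rows(net: nx.Graph) -> tuple[list, dict]:
    nodes = list(net.nodes)
    recd = {v: {} for v in nodes}
    for v, dists in nx.all_pairs_shortest_path_length(net):
        for u, d in dists.items():
            if u != v:
                recd[v][u] = 1.0 / d
    return nodes, recd


def assortativity(net: nx.Graph, target: str = "degree") -> dict:
    """Per-node correlation between proximity and a partner metric.

    For node v: Pearson correlation over all other nodes u between
    1/d(v, u) (0 when unreachable) and the target metric of u.  NaN when
    the correlation is undefined (fewer than two partners, or zero
    variance on either side).
    """
    if target == "degree":
        metric = {v: float(d) for v, d in net.degree()}
    elif target == "closeness":
        metric = closeness(net)
    elif target == "betweenness":
        metric = betweenness(net)
    else:
        raise ValueError(f"unknown assortativity target {target!r}")
    nodes, recd = _reciprocal_distance_rows(net)
    out = {}
    for v in nodes:
        others = [u for u in nodes if u != v]
        if len(others) < 2:
            out[v] = math.nan
            continue
        x = np.array([recd[v].get(u, 0.0) for u in others])
        y = np.array([metric[u] for u in others])
        if x.std() == 0 or y.std() == 0:
            out[v] = math.nan
            continue
        out[v] = float(np.corrcoef(x, y)[0, 1])
    return out


def q_dc(
    net: nx.Graph,
    q: int = 1,
    generators: list[CycleRepresentative] | None = None,
    expand_depth: int = 1,
) -> dict:
    """Number of q-dimensional cavities whose cycles involve each node.

    A node is credited for a homology class when it lies on the class's
    minimal representative or on any stored homologous variant; each
    class counts at most once per node.  Only q = 1 is supported (the
    networks analyzed have essentially no higher cavities).
    """
    if q != 1:
        raise NotImplementedError("cycle-involvement degree implemented for q = 1")
    if generators is None:
        complex_ = build_clique_complex(net, max_dim=2)
        generators = homology_generators_1(complex_, expand_depth=expand_depth)
    counts = {v: 0 for v in net.nodes}
    for rep in generators:
        for v in rep.nodes_on_any_variant:
            if v in counts:
                counts[v] += 1
    return counts


@dataclass
class RankedCycle:
    cycle: CycleRepresentative
    rank_value: float

    @property
    def node_list(self) -> tuple:
        return tuple(sorted(self.cycle.nodes))


def rank_cycles(cycles: list[CycleRepresentative], dc: dict) -> list[RankedCycle]:
    """Order cycles by the mean q-DC of their member nodes, descending.

    Ties are broken lexicographically by sorted node list, so the order
    is deterministic.
    """
    ranked = [
        RankedCycle(
            cycle=c,
            rank_value=float(np.mean([dc.get(v, 0) for v in sorted(c.nodes)])) if c.nodes else 0.0,
        )
        for c in cycles
    ]
    ranked.sort(key=lambda r: (-r.rank_value, r.node_list))
    return ranked


def node_metric_table(net: nx.Graph, expand_depth: int = 1) -> pd.DataFrame:
    """One row per node: degree, clustering, betweenness, closeness,
    three assortativities, and 1-DC."""
    deg = degree(net)
    cc = clustering(net)
    bt = betweenness(net)
    cl = closeness(net)
    a_d = assortativity(net, "degree")
    a_c = assortativity(net, "closeness")
    a_b = assortativity(net, "betweenness")
    dc1 = q_dc(net, 1, expand_depth=expand_depth)
    rows = [
        {
            "node": v,
            "degree": deg[v],
            "clustering": cc[v],
            "betweenness": bt[v],
            "closeness": cl[v],
            "assortativity_degree": a_d[v],
            "assortativity_closeness": a_c[v],
            "assortativity_betweenness": a_b[v],
            "dc1": dc1[v],
        }
        for v in sorted(net.nodes, key=str)
    ]
    return pd.DataFrame(rows)
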