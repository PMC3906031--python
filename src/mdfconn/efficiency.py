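"""Latora-Marchiori efficiency and cost of weighted directed networks.

The length of a path is the sum of the reciprocals of the weights of its
edges, so large weights mean short/strong connections.  The efficiency of
a graph G on N vertices is

    E(G) = (1 / (N (N - 1))) * sum_{i != j} 1 / d_ij,

with d_ij the shortest directed path length (1/d = 0 for unreachable
pairs).  Global efficiency normalizes by the ideal graph with every edge
present (same weights); local efficiency averages the normalized
efficiency of each vertex's neighbour subgraph; cost is the realized
weight fraction sum(a w) / sum(w).  All three lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import InvalidNetworkError, UndefinedCostError, UndefinedEfficiencyError
from .netgen import WeightedNetwork

__all__ = ["EfficiencyReport", "path_length_matrix", "graph_efficiency",
           "global_efficiency", "local_efficiency", "network_cost",
           "efficiency_report"]


@dataclass
class EfficiencyReport:
    global_efficiency: float
    local_efficiency: float
    cost: float
    n: int

    def as_dict(self) -> dict:
        return {"global_efficiency": self.global_efficiency,
                "local_efficiency": self.local_efficiency,
                "cost": self.cost, "n": self.n}


def _as_net(net) -> WeightedNetwork:
    if isinstance(net, WeightedNetwork):
        return net
    raise TypeError("expected a WeightedNetwork")


def _shortest_paths(a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """All-pairs shortest directed path lengths with edge lengths 1/w on
    existing edges; +inf marks unreachable pairs."""
    n = len(a)
    ii, jj = np.nonzero(a)
    if np.any(w[ii, jj] <= 0):
        raise InvalidNetworkError("existing edge with non-positive weight")
    lengths = csr_matrix((1.0 / w[ii, jj], (ii, jj)), shape=(n, n))
    return shortest_path(lengths, method="D", directed=True)


def path_length_matrix(net: WeightedNetwork) -> np.ndarray:
    """Matrix of shortest directed path lengths d_ij (inf if unreachable)."""
    net = _as_net(net)
    return _shortest_paths(net.adjacency, net.weights)


def _efficiency_from_paths(d: np.ndarray) -> float:
    n = len(d)
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def graph_efficiency(a: np.ndarray, w: np.ndarray) -> float:
    """Unnormalized efficiency E(G) of the graph (a, w)."""
    return _efficiency_from_paths(_shortest_paths(a, w))


def _ideal_adjacency(n: int) -> np.ndarray:
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return a


def global_efficiency(net: WeightedNetwork) -> float:
    """E_glob = E(G) / E(G_ideal); G_ideal has every edge present with the
    same weight matrix (pairs with zero weight stay unreachable)."""
    net = _as_net(net)
    n = net.n
    if n < 2:
        raise ValueError("need at least 2 vertices")
    e = graph_efficiency(net.adjacency, net.weights)
    ideal = _ideal_adjacency(n) & (net.weights > 0).astype(np.int8)
    e_ideal = graph_efficiency(ideal, net.weights)
    if e_ideal == 0:
        raise UndefinedEfficiencyError("ideal graph has zero efficiency")
    return e / e_ideal


def local_efficiency(net: WeightedNetwork) -> float:
    """Mean over vertices of E(G_i)/E(G_i_ideal) on the subgraph induced by
    the neighbours of i (union of in- and out-neighbours); vertices with
    fewer than 2 neighbours contribute 0."""
    net = _as_net(net)
    a, w = net.adjacency, net.weights
    n = net.n
    if n < 2:
        raise ValueError("need at least 2 vertices")
    undirected = (a | a.T).astype(bool)
    total = 0.0
    for i in range(n):
        nb = np.nonzero(undirected[i])[0]
        nb = nb[nb != i]
        if len(nb) < 2:
            continue
        a_sub = a[np.ix_(nb, nb)]
        w_sub = w[np.ix_(nb, nb)]
        e = graph_efficiency(a_sub, w_sub)
        ideal = _ideal_adjacency(len(nb)) & (w_sub > 0).astype(np.int8)
        e_ideal = graph_efficiency(ideal, w_sub)
        if e_ideal > 0:
            total += e / e_ideal
    return total / n


def network_cost(net: WeightedNetwork) -> float:
    """Cost = sum_{i != j} a_ij w_ij / sum_{i != j} w_ij."""
    net = _as_net(net)
    w = net.weights.copy()
    np.fill_diagonal(w, 0.0)
    denom = w.sum()
    if denom <= 0:
        raise UndefinedCostError("total weight is zero")
    return float((net.adjacency * w).sum() / denom)


def efficiency_report(net: WeightedNetwork) -> EfficiencyReport:
    return EfficiencyReport(global_efficiency(net), local_efficiency(net),
                            network_cost(net), net.n)
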