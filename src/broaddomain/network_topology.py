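"""Node-topology statistics of an undirected gene network and group comparison.

Five per-node statistics on the (connected) network, all on unweighted hop
distances:

* degree -- neighbour count;
* stress -- total number of shortest paths between other node pairs passing
  through the node (unordered pairs);
* betweenness -- mean over node pairs of the fraction of their shortest
  paths through the node, normalized by (n-1)(n-2)/2 so it lies in [0, 1];
* eccentricity -- largest shortest-path distance to any node;
* avg_shortest_path -- mean shortest-path distance to the other nodes.

Stress and betweenness are accumulated in a single Brandes-style dependency
pass per source; eccentricity and average path length fall out of the same
BFS.  A gene group (e.g. broad-domain-associated genes) is compared against
the remaining nodes with a two-sided Wilcoxon rank-sum test (normal
approximation with tie correction).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "NodeStats",
    "GroupComparison",
    "METRICS",
    "largest_component",
    "node_stats",
    "compare_groups",
]

METRICS = ("degree", "stress", "betweenness", "eccentricity", "avg_shortest_path")


@dataclass(frozen=True)
class NodeStats:
    degree: int
    stress: int
    betweenness: float
    eccentricity: int
    avg_shortest_path: float

    def __post_init__(self):
        if not (0.0 <= self.betweenness <= 1.0 + 1e-12):
            raise ValueError("normalized betweenness must lie in [0, 1]")
        if self.eccentricity < self.avg_shortest_path - 1e-9:
            raise ValueError("eccentricity (a max) cannot undercut the mean distance")


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    median_group: float
    median_rest: float
    ratio: float
    p_value: float
    n_group: int
    n_rest: int


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties break deterministically toward the lexicographically smallest
    sorted node-id tuple.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = [sorted(c, key=str) for c in nx.connected_components(net)]
    biggest = max(len(c) for c in components)
    best = min(
        (c for c in components if len(c) == biggest),
        key=lambda c: [str(x) for x in c],
    )
    return net.subgraph(best).copy()


def node_stats(net: nx.Graph) -> dict[Hashable, NodeStats]:
    """All five statistics for every node of a connected graph."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(net):
        raise ValueError("graph is disconnected; run largest_component first")
    nodes = list(net.nodes)
    adj = {v: list(net.neighbors(v)) for v in nodes}
    betw = dict.fromkeys(nodes, 0.0)
    stress = dict.fromkeys(nodes, 0.0)
    ecc = {}
    avg = {}
    for s in nodes:
        # BFS with shortest-path counting (sigma) and predecessor lists
        dist = {s: 0}
        sigma = {s: 1}
        preds: dict[Hashable, list] = {s: []}
        order = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    preds[w] = []
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        if n > 1:
            dvals = dist.values()
            ecc[s] = max(dvals)
            avg[s] = sum(dvals) / (n - 1)
        else:
            ecc[s] = 0
            avg[s] = 0.0
        # reverse-topological dependency accumulation (Brandes); delta_b for
        # betweenness, delta_s counts shortest paths from v onward
        delta_b = dict.fromkeys(order, 0.0)
        delta_s = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta_b[v] += sigma[v] / sigma[w] * (1.0 + delta_b[w])
                delta_s[v] += 1.0 + delta_s[w]
            if w is not s:
                betw[w] += delta_b[w]
                stress[w] += sigma[w] * delta_s[w]
    pair_norm = (n - 1) * (n - 2)  # ordered-pair accumulation / 2, then /C(n-1,2)
    out = {}
    for v in nodes:
        out[v] = NodeStats(
            degree=net.degree(v),
            stress=int(round(stress[v] / 2.0)),
            betweenness=(betw[v] / pair_norm) if pair_norm > 0 else 0.0,
            eccentricity=int(ecc[v]),
            avg_shortest_path=float(avg[v]),
        )
    return out


def compare_groups(
    statistics: Mapping[Hashable, NodeStats],
    group: Iterable[Hashable],
    metric: str,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum of one metric, group vs remaining nodes."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    group = set(group)
    unknown = group - set(statistics)
    if unknown:
        raise KeyError(f"group members absent from the network: {sorted(map(str, unknown))[:5]}")
    if not group or len(group) == len(statistics):
        raise ValueError("group must be a nonempty proper subset of the nodes")
    g_vals = np.array([getattr(statistics[v], metric) for v in statistics if v in group], dtype=float)
    r_vals = np.array([getattr(statistics[v], metric) for v in statistics if v not in group], dtype=float)
    # exact null for small tie-free samples, else normal approximation with
    # tie correction (the normal tail is too coarse below ~10 per group)
    pooled = np.concatenate([g_vals, r_vals])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and min(len(g_vals), len(r_vals)) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(g_vals, r_vals, alternative="two-sided", method=method)
    med_g = float(np.median(g_vals))
    med_r = float(np.median(r_vals))
    if med_r != 0:
        ratio = med_g / med_r
    else:
        ratio = float("inf") if med_g > 0 else float("nan")
    return GroupComparison(
        metric=metric, median_group=med_g, median_rest=med_r, ratio=ratio,
        p_value=float(res.pvalue), n_group=len(g_vals), n_rest=len(r_vals),
    )
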