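"""Centrality statistics: closed forms, brute-force oracle, group comparison."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from broaddomain.network_topology import (
    METRICS,
    NodeStats,
    compare_groups,
    largest_component,
    node_stats,
)
from broaddomain.synthetic_data import SyntheticConfig, generate_network


def brute_force_stats(G):
    """Independent oracle: all-pairs BFS + shortest-path enumeration by
    DAG counting, accumulating stress/betweenness pair by pair."""
    nodes = list(G.nodes)
    n = len(nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1}
        q = deque([s])
        while q:
            v = q.popleft()
            for w in G.neighbors(v):
                if w not in d:
                    d[w] = d[v] + 1
                    sig[w] = 0
                    q.append(w)
                if d[w] == d[v] + 1:
                    sig[w] += sig[v]
        dist[s] = d
        sigma[s] = sig
    stress = dict.fromkeys(nodes, 0)
    betw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        st = sigma[s][t]
        for v in nodes:
            if v in (s, t):
                continue
            if dist[s][v] + dist[v][t] == dist[s][t]:
                through = sigma[s][v] * sigma[t][v]
                stress[v] += through
                betw[v] += through / st
    norm = (n - 1) * (n - 2) / 2
    return {
        v: NodeStats(
            degree=G.degree(v),
            stress=stress[v],
            betweenness=betw[v] / norm,
            eccentricity=max(dist[v].values()),
            avg_shortest_path=sum(dist[v].values()) / (n - 1),
        )
        for v in nodes
    }


class TestClosedForms:
    def test_path_graph_hand_values(self):
        G = nx.path_graph(["A", "B", "C"])
        s = node_stats(G)
        assert s["B"] == NodeStats(2, 1, 1.0, 1, 1.0)
        assert s["A"] == NodeStats(1, 0, 0.0, 2, 1.5)

    def test_star_center(self):
        G = nx.star_graph(5)  # center 0, leaves 1..5
        s = node_stats(G)
        assert s[0].stress == 10  # C(5,2) leaf pairs
        assert s[0].betweenness == pytest.approx(1.0)
        assert s[0].eccentricity == 1
        assert all(s[v].stress == 0 for v in range(1, 6))

    def test_complete_graph_betweenness_zero(self):
        s = node_stats(nx.complete_graph(6))
        assert all(v.betweenness == 0.0 for v in s.values())


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_random_graph_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            G = nx.gnp_random_graph(30, 0.2, seed=int(rng.integers(2**31)))
            if nx.is_connected(G):
                break
        got = node_stats(G)
        want = brute_force_stats(G)
        for v in G.nodes:
            assert got[v].degree == want[v].degree
            assert got[v].stress == want[v].stress
            assert got[v].betweenness == pytest.approx(want[v].betweenness, abs=1e-9)
            assert got[v].eccentricity == want[v].eccentricity
            assert got[v].avg_shortest_path == pytest.approx(want[v].avg_shortest_path)

    def test_betweenness_matches_networkx(self):
        G = nx.gnp_random_graph(40, 0.15, seed=33)
        G = largest_component(G)
        got = node_stats(G)
        ref = nx.betweenness_centrality(G, normalized=True)
        for v in G.nodes:
            assert got[v].betweenness == pytest.approx(ref[v], abs=1e-9)

    def test_stress_sum_identity(self):
        # sum_v stress(v) = sum over pairs of sigma_st * (d_st - 1)
        G = largest_component(nx.gnp_random_graph(25, 0.2, seed=5))
        s = node_stats(G)
        total = sum(v.stress for v in s.values())
        dist = dict(nx.all_pairs_shortest_path_length(G))
        expect = 0
        for a, b in itertools.combinations(G.nodes, 2):
            n_paths = len(list(nx.all_shortest_paths(G, a, b)))
            expect += n_paths * (dist[a][b] - 1)
        assert total == expect

    def test_eccentricity_bounds_mean_distance(self):
        G = largest_component(nx.gnp_random_graph(30, 0.15, seed=10))
        for v, s in node_stats(G).items():
            assert s.eccentricity >= s.avg_shortest_path


class TestLargestComponent:
    def test_connected_graph_is_itself(self):
        G = nx.path_graph(5)
        assert set(largest_component(G).nodes) == set(G.nodes)

    def test_picks_bigger_component(self):
        G = nx.Graph()
        G.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        G.add_edges_from([("x", "y"), ("y", "z")])
        assert set(largest_component(G).nodes) == {"a", "b", "c", "d", "e"}

    def test_size_matches_union_find_oracle(self):
        rng = np.random.default_rng(13)
        G = nx.gnp_random_graph(80, 0.02, seed=13)
        parent = list(range(80))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in G.edges:
            parent[find(u)] = find(v)
        sizes = {}
        for x in range(80):
            sizes[find(x)] = sizes.get(find(x), 0) + 1
        assert largest_component(G).number_of_nodes() == max(sizes.values())

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            largest_component(nx.Graph())

    def test_disconnected_node_stats_rejected(self):
        G = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="largest_component"):
            node_stats(G)


class TestCompareGroups:
    def test_symmetric_split_of_cycle_has_no_signal(self):
        G = nx.cycle_graph(24)  # vertex-transitive: every node identical
        s = node_stats(G)
        res = compare_groups(s, set(range(12)), "degree")
        assert res.ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_hubs_recovered(self):
        cfg = SyntheticConfig(seed=21, network_nodes=500, n_planted_hubs=15)
        G, hubs, _ = generate_network(cfg)
        s = node_stats(largest_component(G))
        res = compare_groups(s, hubs, "degree")
        assert res.ratio > 2
        assert res.p_value < 0.01

    def test_empty_or_full_group_rejected(self):
        s = node_stats(nx.path_graph(5))
        with pytest.raises(ValueError):
            compare_groups(s, set(), "degree")
        with pytest.raises(ValueError):
            compare_groups(s, set(range(5)), "degree")

    def test_unknown_metric_rejected(self):
        s = node_stats(nx.path_graph(4))
        with pytest.raises(ValueError):
            compare_groups(s, {0}, "pagerank")

    def test_p_close_to_exact_permutation_for_small_groups(self):
        # rank-sum p from the implementation vs an independent Monte-Carlo
        # permutation oracle of the same statistic (40k draws, se < 0.003)
        rng = np.random.default_rng(99)
        n_perm = 40_000
        for _ in range(200):
            n_g = int(rng.integers(3, 11))
            n_r = int(rng.integers(30, 50))
            values = rng.normal(size=n_g + n_r)  # continuous -> tie-free
            stats_map = {
                i: NodeStats(degree=1, stress=0, betweenness=0.0,
                             eccentricity=100, avg_shortest_path=float(10 + v))
                for i, v in enumerate(values)
            }
            group = set(range(n_g))
            res = compare_groups(stats_map, group, "avg_shortest_path")
            ranks = sps.rankdata(values)
            w_obs = ranks[:n_g].sum()
            perms = rng.permuted(
                np.tile(ranks, (n_perm, 1)), axis=1
            )[:, :n_g].sum(axis=1)
            lo = (perms <= w_obs + 1e-9).mean()
            hi = (perms >= w_obs - 1e-9).mean()
            oracle = min(1.0, 2.0 * min(lo, hi))  # doubled-tail two-sided
            assert abs(res.p_value - oracle) < 0.012


def test_generate_network_tree_when_m_is_one():
    cfg = SyntheticConfig(seed=3, network_nodes=50, network_m=1)
    G, _, _ = generate_network(cfg)
    assert G.number_of_edges() == 49
    assert nx.is_connected(G)
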