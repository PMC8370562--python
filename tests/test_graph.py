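import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import srofluency as sf
from srofluency.correlations import CorrelationMatrix
from srofluency.graph import (
    FeatureGraph,
    betweenness,
    build_graph,
    degree,
    global_efficiency,
    graph_cost_efficiency,
    local_efficiency,
    nodal_metrics,
    select_edge_rule,
    shortest_paths,
)

from oracles import (
    betweenness_bf,
    degree_bf,
    global_efficiency_bf,
    local_efficiency_bf,
)


def graph_from_adj(adj):
    adj = np.asarray(adj)
    return FeatureGraph(tuple(f"n{i}" for i in range(adj.shape[0])), adj)


def matrix_from_p(p, features=None):
    p = np.asarray(p, dtype=float)
    k = p.shape[0]
    features = features or tuple(f"f{i}" for i in range(k))
    idx = pd.Index(features)
    rho = pd.DataFrame(np.zeros((k, k)), index=idx, columns=idx)
    return CorrelationMatrix(
        "p", tuple(features),
        rho,
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(np.full((k, k), 30), index=idx, columns=idx),
    )


def test_build_graph_strict_threshold():
    p = np.array(
        [[0.0, 0.05, 0.01], [0.05, 0.0, 0.002], [0.01, 0.002, 0.0]]
    )
    g = build_graph(matrix_from_p(p), alpha=0.05)
    # p == alpha exactly forms no edge; p < alpha does
    assert g.adjacency[0, 1] == 0
    assert g.adjacency[0, 2] == 1
    assert g.adjacency[1, 2] == 1
    assert g.n_edges == 2
    with pytest.raises(ValueError):
        build_graph(matrix_from_p(p), alpha=1.5)


def test_build_graph_missing_p_and_empty():
    p = np.full((3, 3), np.nan)
    g = build_graph(matrix_from_p(p), 0.05)
    assert g.n_edges == 0
    assert all(degree(g, i) == 0 for i in range(3))


def test_shortest_paths_examples():
    path = graph_from_adj([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    d = shortest_paths(path)
    assert d[0, 2] == 2
    disconnected = graph_from_adj([[0, 0], [0, 0]])
    assert math.isinf(shortest_paths(disconnected)[0, 1])
    k5 = graph_from_adj(1 - np.eye(5, dtype=int))
    d5 = shortest_paths(k5)
    assert (d5[~np.eye(5, dtype=bool)] == 1).all()


def test_complete_graph_closed_forms():
    g = graph_from_adj(1 - np.eye(4, dtype=int))
    for i in range(4):
        m = nodal_metrics(g, i)
        assert m.degree == 3
        assert m.betweenness == 0.0
        assert m.global_efficiency == 1.0
        assert m.local_efficiency == 1.0
        assert m.cost == 1.0


def test_star_graph_betweenness():
    # K1,3: every ordered leaf pair routes through the centre
    adj = np.zeros((4, 4), dtype=int)
    adj[0, 1:] = adj[1:, 0] = 1
    g = graph_from_adj(adj)
    assert betweenness(g, 0) == pytest.approx(6 / ((4 - 1) * (4 - 2)))
    assert betweenness(g, 0) == pytest.approx(betweenness_bf(adj, 0))
    for leaf in (1, 2, 3):
        assert betweenness(g, leaf) == 0.0


def test_path_graph_hand_computation():
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    g = graph_from_adj(adj)
    assert global_efficiency(g, 0) == pytest.approx((1 + 0.5) / 2)
    assert local_efficiency(g, 1) == 0.0  # neighbours A, C not adjacent
    assert graph_cost_efficiency(g) == pytest.approx(
        (0.75 + 1 + 0.75) / 3 - (0.5 + 1 + 0.5) / 3
    )


def test_isolated_node_metrics_are_zero():
    adj = np.zeros((4, 4), dtype=int)
    adj[1, 2] = adj[2, 1] = 1
    g = graph_from_adj(adj)
    m = nodal_metrics(g, 0)
    assert (m.degree, m.betweenness, m.global_efficiency, m.local_efficiency, m.cost) == (
        0, 0.0, 0.0, 0.0, 0.0,
    )


def _random_adj(rng, n):
    adj = (rng.random((n, n)) < rng.uniform(0.15, 0.8)).astype(int)
    adj = np.triu(adj, 1)
    return adj + adj.T


@pytest.mark.parametrize("seed", range(5))
def test_metrics_match_networkx(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        n = int(rng.integers(3, 8))
        adj = _random_adj(rng, n)
        g = graph_from_adj(adj)
        G = nx.from_numpy_array(adj)
        btw = nx.betweenness_centrality(G, normalized=True)
        for i in range(n):
            assert degree(g, i) == G.degree[i]
            assert betweenness(g, i) == pytest.approx(btw[i], abs=1e-12)
            # nodal global efficiency from nx shortest paths
            lengths = nx.single_source_shortest_path_length(G, i)
            eff = sum(1 / d for node, d in lengths.items() if node != i) / (n - 1)
            assert global_efficiency(g, i) == pytest.approx(eff, abs=1e-12)
            nbrs = list(G[i])
            if len(nbrs) >= 2:
                sub = G.subgraph(nbrs)
                assert local_efficiency(g, i) == pytest.approx(
                    nx.global_efficiency(sub), abs=1e-12
                )


def test_metrics_match_brute_force_sample():
    rng = np.random.default_rng(99)
    for _ in range(60):
        n = int(rng.integers(2, 7))
        adj = _random_adj(rng, n)
        g = graph_from_adj(adj)
        for i in range(n):
            assert degree(g, i) == degree_bf(adj, i)
            assert betweenness(g, i) == pytest.approx(betweenness_bf(adj, i), abs=1e-12)
            assert global_efficiency(g, i) == pytest.approx(
                global_efficiency_bf(adj, i), abs=1e-12
            )
            assert local_efficiency(g, i) == pytest.approx(
                local_efficiency_bf(adj, i), abs=1e-12
            )


def test_adding_an_edge_is_monotone():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = 6
        adj = _random_adj(rng, n)
        empty_pairs = [
            (i, j) for i, j in itertools.combinations(range(n), 2) if not adj[i, j]
        ]
        if not empty_pairs:
            continue
        i, j = empty_pairs[int(rng.integers(len(empty_pairs)))]
        g_before = graph_from_adj(adj)
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        g_after = graph_from_adj(adj2)
        for v in range(n):
            assert degree(g_after, v) >= degree(g_before, v)
            assert global_efficiency(g_after, v) >= global_efficiency(g_before, v) - 1e-12


def test_select_edge_rule_prefers_efficient_alpha():
    rng = np.random.default_rng(10)
    matrices = []
    for pid in range(12):
        # p-values between 0.012 and 0.3: the 0.05 rule keeps a moderately
        # dense graph (positive cost efficiency) while 0.01 keeps none
        p = rng.uniform(0.012, 0.3, size=(17, 17))
        p = np.triu(p, 1) + np.triu(p, 1).T
        m = matrix_from_p(p, features=sf.FEATURE_NAMES)
        m.participant_id = f"p{pid}"
        matrices.append(m)
    report = select_edge_rule(matrices)
    assert report.selected_alpha == 0.05
    assert report.p < 0.05
    assert report.df == 11


def test_select_edge_rule_identical_alphas():
    rng = np.random.default_rng(11)
    matrices = []
    for pid in range(4):
        p = rng.uniform(0.2, 0.9, size=(17, 17))  # no edges under either rule
        p = np.triu(p, 1) + np.triu(p, 1).T
        matrices.append(matrix_from_p(p, features=sf.FEATURE_NAMES))
    report = select_edge_rule(matrices)
    assert report.statistic == 0.0
    assert "no difference" in report.note
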