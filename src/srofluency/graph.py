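"""Binary feature graphs from correlation significance, and nodal metrics.

Each participant's 17 features become nodes; an unweighted, undirected
edge joins two features when their Spearman correlation is significant
(p strictly below the chosen alpha). Four nodal metrics characterise a
node i in a graph of N nodes:

* degree          — number of incident edges,
* betweenness     — sum over ordered pairs (j, k), j,k != i, of the
                    fraction of shortest j-k paths through i, divided by
                    (N-1)(N-2),
* global efficiency — mean over j != i of 1/P(i, j) (1/inf = 0),
* local efficiency  — mean over ordered pairs of distinct neighbours
                    (j, k) of 1/P'(j, k), where P' is the shortest path
                    inside the subgraph induced by i's neighbours
                    (i itself removed); 0 when degree < 2.

Cost of a node is degree/(N-1); a graph's cost efficiency is the mean
nodal global efficiency minus the mean nodal cost, and is used to pick
the edge-forming alpha (0.05 vs 0.01) by a paired t-test across the
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlations import CorrelationMatrix

__all__ = [
    "FeatureGraph",
    "NodalMetrics",
    "EdgeRuleReport",
    "build_graph",
    "shortest_paths",
    "degree",
    "betweenness",
    "global_efficiency",
    "local_efficiency",
    "nodal_metrics",
    "graph_cost_efficiency",
    "select_edge_rule",
]


@dataclass
class FeatureGraph:
    """Unweighted undirected graph on feature nodes."""

    nodes: tuple[str, ...]
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal
    alpha: float | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node count")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index(self, node: str | int) -> int:
        if isinstance(node, str):
            try:
                return self.nodes.index(node)
            except ValueError:
                raise KeyError(f"unknown node {node!r}") from None
        if not 0 <= node < self.n_nodes:
            raise KeyError(f"node index {node} out of range")
        return node

    def edge_list(self) -> list[tuple[str, str]]:
        return [
            (self.nodes[i], self.nodes[j])
            for i in range(self.n_nodes)
            for j in range(i + 1, self.n_nodes)
            if self.adjacency[i, j]
        ]


def build_graph(matrix: CorrelationMatrix, alpha: float = 0.05) -> FeatureGraph:
    """Threshold a correlation matrix into a binary graph (p < alpha).

    A missing p-value never forms an edge.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = matrix.p.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        adj = (p < alpha).astype(int)
    np.fill_diagonal(adj, 0)
    return FeatureGraph(tuple(matrix.features), adj, alpha=alpha)


def shortest_paths(graph: FeatureGraph) -> np.ndarray:
    """All-pairs BFS distances in edges; np.inf where disconnected."""
    n = graph.n_nodes
    adj = graph.adjacency
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0.0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def _path_counts(graph: FeatureGraph) -> tuple[np.ndarray, np.ndarray]:
    """BFS distances and shortest-path counts sigma[s, t] for all pairs."""
    n = graph.n_nodes
    adj = graph.adjacency
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
                    if dist[s, v] == d:
                        sigma[s, v] += sigma[s, u]
            frontier = nxt
    return dist, sigma


def degree(graph: FeatureGraph, node: str | int) -> int:
    """Number of edges incident to the node."""
    return int(graph.adjacency[graph.index(node)].sum())


def betweenness(graph: FeatureGraph, node: str | int) -> float:
    """Fractional betweenness centrality, normalised by (N-1)(N-2)."""
    i = graph.index(node)
    n = graph.n_nodes
    if n < 3:
        return 0.0
    dist, sigma = _path_counts(graph)
    total = 0.0
    for j in range(n):
        if j == i:
            continue
        for k in range(n):
            if k in (i, j):
                continue
            if not np.isfinite(dist[j, k]) or sigma[j, k] == 0:
                continue
            if dist[j, i] + dist[i, k] == dist[j, k]:
                total += sigma[j, i] * sigma[i, k] / sigma[j, k]
    return total / ((n - 1) * (n - 2))


def global_efficiency(graph: FeatureGraph, node: str | int) -> float:
    """Mean inverse shortest-path length from the node to all others."""
    i = graph.index(node)
    n = graph.n_nodes
    if n < 2:
        return 0.0
    dist = shortest_paths(graph)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[i]
    inv[i] = 0.0
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n - 1))


def local_efficiency(graph: FeatureGraph, node: str | int) -> float:
    """Efficiency inside the subgraph induced by the node's neighbours.

    Mean of 1/P'(j, k) over ordered pairs of distinct neighbours, with
    paths restricted to the neighbour subgraph (the node itself removed);
    0 when the node has fewer than two neighbours.
    """
    i = graph.index(node)
    nbrs = np.flatnonzero(graph.adjacency[i])
    d = len(nbrs)
    if d < 2:
        return 0.0
    sub_adj = graph.adjacency[np.ix_(nbrs, nbrs)]
    sub = FeatureGraph(tuple(graph.nodes[j] for j in nbrs), sub_adj)
    dist = shortest_paths(sub)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (d * (d - 1)))


@dataclass(frozen=True)
class NodalMetrics:
    node: str
    degree: int
    betweenness: float
    global_efficiency: float
    local_efficiency: float
    cost: float


def nodal_metrics(graph: FeatureGraph, node: str | int) -> NodalMetrics:
    """All four nodal metrics plus cost = degree/(N-1) for one node."""
    i = graph.index(node)
    d = degree(graph, i)
    return NodalMetrics(
        node=graph.nodes[i],
        degree=d,
        betweenness=betweenness(graph, i),
        global_efficiency=global_efficiency(graph, i),
        local_efficiency=local_efficiency(graph, i),
        cost=d / (graph.n_nodes - 1) if graph.n_nodes > 1 else 0.0,
    )


def graph_cost_efficiency(graph: FeatureGraph) -> float:
    """Mean nodal global efficiency minus mean nodal cost."""
    n = graph.n_nodes
    if n < 2:
        return 0.0
    dist = shortest_paths(graph)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    eff = inv.sum(axis=1) / (n - 1)
    cost = graph.adjacency.sum(axis=1) / (n - 1)
    return float(eff.mean() - cost.mean())


@dataclass
class EdgeRuleReport:
    """Paired comparison of graph cost efficiency across edge-rule alphas."""

    alphas: tuple[float, float]
    cost_efficiency: pd.DataFrame  # one row per participant, one column per alpha
    statistic: float
    df: int
    p: float
    selected_alpha: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "alphas": list(self.alphas),
            "mean_cost_efficiency": {
                str(a): float(self.cost_efficiency[a].mean()) for a in self.alphas
            },
            "t": self.statistic,
            "df": self.df,
            "p": self.p,
            "selected_alpha": self.selected_alpha,
            "note": self.note,
        }


def select_edge_rule(
    matrices: Sequence[CorrelationMatrix],
    alphas: Iterable[float] = (0.05, 0.01),
) -> EdgeRuleReport:
    """Choose the edge-forming alpha with significantly higher cost efficiency.

    Builds both graphs per participant, computes graph cost efficiency,
    and compares the two alphas with a paired two-tailed t-test.
    """
    alphas = tuple(alphas)
    if len(alphas) != 2:
        raise ValueError("exactly two candidate alphas are compared")
    if len(matrices) < 2:
        raise ValueError("need at least two participants")
    ce = {
        a: [graph_cost_efficiency(build_graph(m, a)) for m in matrices] for a in alphas
    }
    df_ce = pd.DataFrame(ce, index=[m.participant_id for m in matrices])
    x, y = df_ce[alphas[0]].to_numpy(), df_ce[alphas[1]].to_numpy()
    note = ""
    if np.allclose(x, y):
        stat, p = 0.0, 1.0
        selected = 0.05 if 0.05 in alphas else alphas[0]
        note = "no difference in cost efficiency; defaulting"
    else:
        stat, p = stats.ttest_rel(x, y)
        stat, p = float(stat), float(p)
        selected = alphas[0] if x.mean() > y.mean() else alphas[1]
        if p >= 0.05:
            note = "difference not significant at 0.05"
    return EdgeRuleReport(
        alphas=alphas,
        cost_efficiency=df_ce,
        statistic=stat,
        df=len(matrices) - 1,
        p=p,
        selected_alpha=selected,
        note=note,
    )
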