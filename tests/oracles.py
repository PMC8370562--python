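"""Independent brute-force oracles used only by the test suite.

Graph metrics are recomputed by exhaustive path enumeration (feasible on
tiny graphs) rather than BFS, so the implementation and the oracle share
no code path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """All simple paths from s to t, by depth-first enumeration."""
    n = adj.shape[0]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(tuple(path))
            return
        for v in range(n):
            if adj[last, v] and v not in path:
                extend(path + [v])

    extend([s])
    return paths


def shortest_paths_bf(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    if s == t:
        return [(s,)]
    paths = enumerate_paths(adj, s, t)
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def distance_bf(adj: np.ndarray, s: int, t: int) -> float:
    sp = shortest_paths_bf(adj, s, t)
    return len(sp[0]) - 1 if sp else math.inf


def degree_bf(adj: np.ndarray, i: int) -> int:
    return int(adj[i].sum())


def betweenness_bf(adj: np.ndarray, i: int) -> float:
    n = adj.shape[0]
    if n < 3:
        return 0.0
    total = 0.0
    for j, k in itertools.permutations(range(n), 2):
        if i in (j, k):
            continue
        sp = shortest_paths_bf(adj, j, k)
        if not sp:
            continue
        through = sum(1 for p in sp if i in p)
        total += through / len(sp)
    return total / ((n - 1) * (n - 2))


def global_efficiency_bf(adj: np.ndarray, i: int) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    s = 0.0
    for j in range(n):
        if j == i:
            continue
        d = distance_bf(adj, i, j)
        if math.isfinite(d) and d > 0:
            s += 1.0 / d
    return s / (n - 1)


def local_efficiency_bf(adj: np.ndarray, i: int) -> float:
    nbrs = [j for j in range(adj.shape[0]) if adj[i, j]]
    d = len(nbrs)
    if d < 2:
        return 0.0
    sub = adj[np.ix_(nbrs, nbrs)]
    s = 0.0
    for a, b in itertools.permutations(range(d), 2):
        dist = distance_bf(sub, a, b)
        if math.isfinite(dist) and dist > 0:
            s += 1.0 / dist
    return s / (d * (d - 1))


def levenshtein_bf(a: str, b: str) -> int:
    """Plain recursive edit distance, for short strings only."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[-1] == b[-1] else 1
    return min(
        levenshtein_bf(a[:-1], b) + 1,
        levenshtein_bf(a, b[:-1]) + 1,
        levenshtein_bf(a[:-1], b[:-1]) + cost,
    )
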