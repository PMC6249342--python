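"""Independent brute-force reference implementations used as oracles.

These deliberately avoid networkx/igraph/scipy graph code: clustering by
explicit neighbor-pair counting, path lengths by hand-rolled BFS,
betweenness by dynamic-programming shortest-path counting over the BFS
DAG, modularity straight from its defining formula, and connectivity by
BFS reachability.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def neighbors(A: np.ndarray, i: int) -> list[int]:
    return [j for j in range(A.shape[0]) if A[i, j]]


def brute_clustering(A: np.ndarray) -> tuple[np.ndarray, float]:
    n = A.shape[0]
    cc = np.zeros(n)
    for i in range(n):
        nb = neighbors(A, i)
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nb, 2) if A[a, b])
        cc[i] = links / (k * (k - 1) / 2)
    return cc, float(cc.mean())


def bfs_distances(A: np.ndarray, source: int) -> np.ndarray:
    n = A.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in neighbors(A, u):
            if np.isinf(dist[v]):
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_path_length(A: np.ndarray) -> float:
    """Mean shortest-path distance over connected unordered pairs."""
    n = A.shape[0]
    vals = []
    for i in range(n):
        d = bfs_distances(A, i)
        vals.extend(d[j] for j in range(i + 1, n) if np.isfinite(d[j]))
    return float(np.mean(vals))


def brute_unreachable_pairs(A: np.ndarray) -> int:
    n = A.shape[0]
    cnt = 0
    for i in range(n):
        d = bfs_distances(A, i)
        cnt += sum(1 for j in range(i + 1, n) if np.isinf(d[j]))
    return cnt


def _path_counts(A: np.ndarray, source: int) -> tuple[np.ndarray, np.ndarray]:
    """BFS distances from ``source`` and the number of shortest paths from
    ``source`` to every node, by level-order dynamic programming."""
    n = A.shape[0]
    dist = bfs_distances(A, source)
    nsp = np.zeros(n)
    nsp[source] = 1
    finite = dist[np.isfinite(dist)]
    for d in range(1, int(finite.max()) + 1):
        for v in range(n):
            if dist[v] == d:
                nsp[v] = sum(nsp[u] for u in neighbors(A, v)
                             if dist[u] == d - 1)
    return dist, nsp


def brute_betweenness(A: np.ndarray) -> np.ndarray:
    """Pair-count betweenness: sum over unordered pairs (s, t) of the
    fraction of shortest s-t paths through each interior node. Uses the
    identity #paths(s->t via v) = #paths(s->v) * #paths(v->t) on the
    shortest-path DAG."""
    n = A.shape[0]
    dist = np.empty((n, n))
    nsp = np.empty((n, n))
    for s in range(n):
        dist[s], nsp[s] = _path_counts(A, s)
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if np.isinf(dist[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[t, v] == dist[s, t]:
                    b[v] += nsp[s, v] * nsp[t, v] / nsp[s, t]
    return b


def brute_modularity(A: np.ndarray, membership) -> float:
    """Q = sum_m [e_mm/E - a_m^2] evaluated edge by edge."""
    membership = np.asarray(membership)
    edges = [(i, j) for i in range(A.shape[0]) for j in range(i + 1, A.shape[0])
             if A[i, j]]
    E = len(edges)
    q = 0.0
    for mod in np.unique(membership):
        e_mm = sum(1 for i, j in edges
                   if membership[i] == mod and membership[j] == mod) / E
        ends = sum(int(membership[i] == mod) + int(membership[j] == mod)
                   for i, j in edges)
        q += e_mm - (ends / (2 * E)) ** 2
    return q


def brute_is_connected(A: np.ndarray) -> bool:
    return bool(np.all(np.isfinite(bfs_distances(A, 0))))


def random_connected_graph(rng: np.random.Generator, n: int,
                           p: float = 0.4, max_tries: int = 200) -> np.ndarray:
    """A random Erdos-Renyi adjacency conditioned on connectivity."""
    for _ in range(max_tries):
        A = (rng.random((n, n)) < p).astype(np.int8)
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() and brute_is_connected(A):
            return A
    raise RuntimeError("could not draw a connected graph")


def all_labeled_graphs(n: int):
    """All labeled simple graphs on n nodes as adjacency matrices."""
    pairs = list(combinations(range(n), 2))
    for code in range(2 ** len(pairs)):
        A = np.zeros((n, n), dtype=np.int8)
        for b, (i, j) in enumerate(pairs):
            if code >> b & 1:
                A[i, j] = A[j, i] = 1
        yield A
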