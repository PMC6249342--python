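"""Global and nodal measures on binary undirected graphs, with
degree-preserving random-graph references.

Global measures
---------------
* clustering coefficient C — mean over nodes of the fraction of realized
  links among each node's neighbors (nodes of degree < 2 contribute 0);
* characteristic path length L — mean shortest-path distance over connected
  node pairs (disconnected pairs are excluded and counted, so graphs below
  the fragmentation density do not crash; a harmonic-mean variant is also
  available);
* gamma = C / C_null, lambda = L / L_null, sigma = gamma / lambda — the
  small-world index, with C_null / L_null the means over an ensemble of
  degree-preserving rewired (double-edge-swap) null graphs;
* modularity Q = sum_m [ e_mm / E - (a_m)^2 ] of the partition found by
  seeded Leiden modularity maximization (CNM greedy and an exhaustive
  small-graph search are available as alternatives).

Nodal measures
--------------
Betweenness centrality (raw pair-count form) and degree, each optionally
normalized by the network-wide mean of the measure. Hubs are nodes whose
betweenness is at least 2 SD above the network mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import BinaryGraph

logger = logging.getLogger(__name__)


def _adj(G) -> np.ndarray:
    if isinstance(G, BinaryGraph):
        return np.asarray(G.adjacency)
    A = np.asarray(G)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return A


def _to_igraph(A: np.ndarray) -> ig.Graph:
    ei, ej = np.nonzero(np.triu(A, k=1))
    return ig.Graph(n=A.shape[0], edges=list(zip(ei.tolist(), ej.tolist())))


def leiden_membership(g: ig.Graph, seed: int = 0,
                      n_iterations: int = -1) -> list[int]:
    """Leiden community detection (modularity objective) with the igraph
    RNG seeded immediately before the call, so results are reproducible."""
    import random

    ig.set_random_number_generator(random.Random(seed))
    return g.community_leiden(objective_function="modularity",
                              n_iterations=n_iterations).membership


def clustering_coefficient(G) -> tuple[np.ndarray, float]:
    """Per-node clustering (triangles / possible neighbor pairs) and mean C."""
    A = _adj(G).astype(float)
    k = A.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, triangles / denom, 0.0)
    return cc, float(cc.mean())


def _distances(A: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(A != 0), method="D", unweighted=True)


def unreachable_pairs(G) -> int:
    """Number of unordered node pairs with no connecting path."""
    d = _distances(_adj(G))
    n = d.shape[0]
    return int((np.isinf(d).sum()) // 2)


def characteristic_path_length(G, mode: str = "exclude") -> float:
    """Mean shortest-path length over node pairs.

    mode="exclude" averages over connected pairs only (default);
    mode="harmonic" returns the harmonic mean with unreachable pairs
    contributing zero reciprocal distance.
    """
    A = _adj(G)
    if A.sum() == 0:
        raise ValueError("path length undefined on a graph with no edges")
    d = _distances(A)
    iu = np.triu_indices(d.shape[0], k=1)
    dv = d[iu]
    finite = np.isfinite(dv)
    if mode == "exclude":
        return float(dv[finite].mean())
    if mode == "harmonic":
        inv = np.where(finite, 1.0 / np.where(finite, dv, 1.0), 0.0)
        return float(len(dv) / inv.sum())
    raise ValueError(f"unknown mode {mode!r}")


def degree(G) -> np.ndarray:
    """Node degrees (adjacency row sums)."""
    return _adj(G).astype(int).sum(axis=1)


def betweenness(G) -> np.ndarray:
    """Raw betweenness: per node, the sum over unordered pairs (s, t) of the
    fraction of shortest s-t paths passing through it."""
    A = _adj(G)
    return np.asarray(_to_igraph(A).betweenness(), dtype=float)


def normalize_by_mean(values: np.ndarray) -> np.ndarray:
    """Divide by the network-wide mean; returned unchanged if the mean is 0."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    return values / m if m != 0 else values.copy()


def null_ensemble(G, n_null: int = 20, seed: int = 0,
                  swaps_per_edge: int = 10) -> list[np.ndarray]:
    """Degree-preserving rewired null graphs (repeated double-edge swaps).

    Every member has exactly the original degree sequence and no self-loops
    or multi-edges. Graphs admitting no swap (e.g. complete graphs) yield
    copies, with a warning.
    """
    A = _adj(G)
    E = int(A.sum()) // 2
    if E < 2:
        raise ValueError("null ensemble needs at least 2 edges")
    base = nx.from_numpy_array(A)
    nswap = swaps_per_edge * E
    seeds = np.random.SeedSequence(seed).generate_state(n_null) % (2**31 - 1)
    out = []
    for s in seeds:
        H = base.copy()
        try:
            nx.double_edge_swap(H, nswap=nswap, max_tries=100 * nswap,
                                seed=int(s))
        except nx.NetworkXError:
            logger.warning("degree-preserving rewiring impossible; "
                           "null member is a copy of the input graph")
        except nx.NetworkXAlgorithmError:
            logger.warning("rewiring hit max_tries; null member uses the "
                           "swaps achieved so far")
        out.append(nx.to_numpy_array(H, nodelist=sorted(H.nodes()), dtype=np.int8))
    return out


@dataclass
class SmallWorld:
    gamma: float
    lam: float
    sigma: float
    C: float
    L: float
    C_null: float
    L_null: float


def small_world(G, ensemble: list[np.ndarray]) -> SmallWorld:
    """gamma = C/C_null, lambda = L/L_null, sigma = gamma/lambda against the
    ensemble means."""
    if not ensemble:
        raise ValueError("null ensemble is empty")
    _, C = clustering_coefficient(G)
    L = characteristic_path_length(G)
    C_null = float(np.mean([clustering_coefficient(H)[1] for H in ensemble]))
    L_null = float(np.mean([characteristic_path_length(H) for H in ensemble]))
    if C_null == 0:
        raise ValueError("C_null is zero; gamma undefined")
    gamma = C / C_null
    lam = L / L_null
    return SmallWorld(gamma, lam, gamma / lam, C, L, C_null, L_null)


def modularity(G, method: str = "leiden", seed: int = 0,
               n_iterations: int = -1) -> tuple[float, np.ndarray]:
    """Modularity Q and membership of the detected partition.

    method="leiden" (default) is Leiden local-moving modularity
    maximization with an explicitly seeded RNG, hence deterministic;
    method="greedy" is CNM greedy agglomeration; method="exhaustive"
    searches all partitions (graphs <= 12 nodes only) and returns the
    global optimum.
    """
    A = _adj(G)
    if A.sum() == 0:
        raise ValueError("modularity needs at least one edge")
    if method == "leiden":
        g = _to_igraph(A)
        membership = np.asarray(
            leiden_membership(g, seed=seed, n_iterations=n_iterations),
            dtype=int)
        return float(g.modularity(membership)), membership
    if method == "greedy":
        g = _to_igraph(A)
        clustering = g.community_fastgreedy().as_clustering()
        membership = np.asarray(clustering.membership, dtype=int)
        return float(g.modularity(membership)), membership
    if method == "exhaustive":
        n = A.shape[0]
        if n > 12:
            raise ValueError("exhaustive partition search limited to <= 12 nodes")
        best_q, best_m = -1.0, None
        for membership in _set_partitions(n):
            q = modularity_fixed(A, membership)
            if q > best_q:
                best_q, best_m = q, membership
        return best_q, np.asarray(best_m, dtype=int)
    raise ValueError(f"unknown method {method!r}")


def _set_partitions(n: int):
    """All set partitions of range(n) as membership arrays (restricted
    growth strings)."""
    m = [0] * n

    def rec(i: int, k: int):
        if i == n:
            yield list(m)
            return
        for c in range(k + 1):
            m[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1) if n > 1 else iter([[0]])


def modularity_fixed(G, membership) -> float:
    """Q = sum_m [ e_mm / E_tot - (a_m)^2 ] for a given partition."""
    A = _adj(G).astype(float)
    membership = np.asarray(membership)
    E = A.sum() / 2.0
    if E == 0:
        raise ValueError("modularity needs at least one edge")
    q = 0.0
    for mod in np.unique(membership):
        mask = membership == mod
        e_mm = A[np.ix_(mask, mask)].sum() / 2.0 / E
        a_m = A[mask].sum() / 2.0 / E  # fraction of edge ends in the module
        q += e_mm - a_m**2
    return q


@dataclass
class NodalMeasures:
    betweenness: np.ndarray
    betweenness_normalized: np.ndarray
    degree: np.ndarray
    degree_normalized: np.ndarray
    node_labels: list[str]


def nodal_measures(G: BinaryGraph) -> NodalMeasures:
    b = betweenness(G)
    k = degree(G)
    return NodalMeasures(b, normalize_by_mean(b), k,
                         normalize_by_mean(k.astype(float)),
                         list(G.node_labels))


@dataclass
class HubSet:
    """Nodes whose centrality exceeds mean + n_sd * SD."""

    members: list[str]
    criterion: float
    universe: list[str]
    n_sd: float = 2.0


def identify_hubs(values: np.ndarray, labels: list[str],
                  n_sd: float = 2.0) -> HubSet:
    """Hubs: value >= mean + n_sd * SD (sample SD). Zero-variance input
    yields an empty hub set."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("hub identification needs >= 3 nodes")
    sd = values.std(ddof=1)
    crit = values.mean() + n_sd * sd
    if sd == 0:
        logger.info("centrality has zero variance; no hubs")
        return HubSet([], float(crit), list(labels), n_sd)
    members = [lab for lab, v in zip(labels, values) if v >= crit]
    return HubSet(members, float(crit), list(labels), n_sd)


@dataclass
class GlobalMeasures:
    density: float
    C: float
    L: float
    gamma: float
    lam: float
    sigma: float
    Q: float
    fragmented: bool
    n_unreachable_pairs: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("density", "C", "L", "gamma", "lam", "sigma", "Q",
                 "fragmented", "n_unreachable_pairs")}


def global_measures(G: BinaryGraph, n_null: int = 20, seed: int = 0) -> GlobalMeasures:
    """All global measures of one graph, nulls included."""
    ens = null_ensemble(G, n_null=n_null, seed=seed)
    sw = small_world(G, ens)
    Q, _ = modularity(G, seed=seed)
    nup = unreachable_pairs(G)
    return GlobalMeasures(G.density, sw.C, sw.L, sw.gamma, sw.lam, sw.sigma,
                          Q, nup > 0, nup)
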