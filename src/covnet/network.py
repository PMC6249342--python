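"""Group-level association matrices and density-thresholded binary graphs.

The structural covariance network is a *group-level* object: entry (i, j)
of the association matrix R is the Pearson correlation of ROI i and ROI j
corrected volumes across the subjects of one group. R is binarized by
keeping the strongest correlations until a target connection density
D = E / [N (N - 1) / 2] is reached; a density sweep (default 0.10-0.50 in
steps of 0.02) yields a nested family of graphs so that topology can be
compared without fixing a single arbitrary threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .synthetic import roi_columns


@dataclass
class AssociationMatrix:
    """Symmetric correlation matrix with zeroed diagonal."""

    values: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("association matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("association matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v
        if len(self.node_labels) != v.shape[0]:
            raise ValueError("node_labels length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected unweighted graph at a stated connection density."""

    adjacency: np.ndarray
    density: float  # achieved density E / [N(N-1)/2]
    edge_count: int
    node_labels: list[str]
    requested_density: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return ncomp == 1


def default_density_grid() -> np.ndarray:
    """The standard sweep: densities 0.10 to 0.50 in 0.02 steps (21 values)."""
    return np.round(np.arange(10, 51, 2) / 100.0, 2)


def density_grid(d_min: float, d_max: float, step: float) -> np.ndarray:
    n = int(round((d_max - d_min) / step)) + 1
    if step <= 0 or n < 1:
        raise ValueError("density grid must be strictly increasing within (0, 1]")
    grid = np.round(d_min + step * np.arange(n), 10)
    if not (np.all(np.diff(grid) > 0) and grid[0] > 0 and grid[-1] <= 1):
        raise ValueError("density grid must be strictly increasing within (0, 1]")
    return grid


def association_matrix(residuals: pd.DataFrame, group: str) -> AssociationMatrix:
    """Pearson correlation of ROI residuals across one group's subjects."""
    sub = residuals.loc[residuals["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has {len(sub)} subjects; "
                         "Pearson correlation needs >= 3")
    cols = roi_columns(residuals)
    Y = sub[cols].to_numpy(dtype=float)
    sds = Y.std(axis=0)
    if (sds == 0).any():
        bad = cols[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"ROI {bad!r} is constant within group {group!r}")
    R = np.corrcoef(Y, rowvar=False)
    np.fill_diagonal(R, 0.0)
    return AssociationMatrix(R, list(cols))


def edge_count_for_density(density: float, n_nodes: int) -> int:
    """Target edge count E = round(D * N(N-1)/2), half away from zero."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density * m + 0.5))


def ranked_edges(values: np.ndarray, absolute: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge indices ordered by decreasing correlation.

    Ties are broken deterministically by (row, column) index so that
    sweeps over nested densities produce nested edge sets.
    """
    iu, ju = np.triu_indices(values.shape[0], k=1)
    vals = values[iu, ju]
    if absolute:
        vals = np.abs(vals)
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def threshold_at_density(R: AssociationMatrix, density: float,
                         absolute: bool = False) -> BinaryGraph:
    """Binarize ``R`` keeping the top-ranked correlations at density ``D``.

    By default edges are the largest *signed* correlations (an edge exists
    where r_ij exceeds the implied threshold); ``absolute=True`` ranks by
    |r_ij| instead.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = R.n_nodes
    m = n * (n - 1) // 2
    e_target = edge_count_for_density(density, n)
    if e_target == 0:
        raise ValueError(f"density {density} yields zero edges for N={n}")
    ei, ej = ranked_edges(R.values, absolute)
    A = np.zeros((n, n), dtype=np.int8)
    A[ei[:e_target], ej[:e_target]] = 1
    A = A | A.T
    return BinaryGraph(A, e_target / m, e_target, list(R.node_labels),
                       requested_density=float(density))


def sweep_densities(R: AssociationMatrix, grid: np.ndarray,
                    absolute: bool = False) -> list[BinaryGraph]:
    """One BinaryGraph per grid density; edge sets are nested along the grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("density grid must be a non-empty increasing 1-D array")
    return [threshold_at_density(R, float(d), absolute=absolute) for d in grid]


def min_connected_density(R: AssociationMatrix, grid: np.ndarray,
                          absolute: bool = False) -> float | None:
    """Smallest grid density whose thresholded graph is a single connected
    component; None if the graph is fragmented at every grid density."""
    for G in sweep_densities(R, grid, absolute=absolute):
        if G.is_connected():
            return G.requested_density
    return None
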