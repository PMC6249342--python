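"""Permutation-based group comparison of covariance-network measures.

Because the covariance network is a group-level statistic, inference uses
subject relabeling: in each permutation the residual volume vectors are
randomly reassigned to two pseudo-groups of the original sizes, both
association matrices are rebuilt, thresholded across the density grid, and
the network measures recomputed — giving the null distribution of the
between-group difference. Two-tailed p-values come from the percentile
position of the observed difference, with a +1 correction so p is never 0:

    p = 2 * min[(1 + #{null >= obs}) / (n_perm + 1),
                (1 + #{null <= obs}) / (n_perm + 1)],  capped at 1.

Density-sweep results are summarized by AUC (trapezoidal integral of the
difference curve over the grid) and an FDA-style functional statistic (the
sum of the difference over grid points), each with its own permutation p.
The permutation scheme itself accounts for multiplicity across densities
and nodes; no further correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .metrics import (HubSet, characteristic_path_length,
                      clustering_coefficient, leiden_membership, null_ensemble)
from .network import default_density_grid, edge_count_for_density, ranked_edges
from .synthetic import roi_columns

_SW_MEASURES = {"gamma", "lambda", "sigma"}
VALID_MEASURES = {"C", "L", "Q"} | _SW_MEASURES


@dataclass
class PermutationConfig:
    """Settings of the subject-relabeling permutation test."""

    n_permutations: int = 1000
    densities: np.ndarray = field(default_factory=default_density_grid)
    measures: tuple[str, ...] = ("Q",)
    seed: int = 0
    alpha: float = 0.05
    #: null-ensemble size for the normalized measures (used inside every
    #: permutation when gamma/lambda/sigma are requested)
    n_null: int = 20
    absolute: bool = False

    def validate(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.measures) - VALID_MEASURES
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        d = np.asarray(self.densities, dtype=float)
        if d.ndim != 1 or len(d) == 0 or np.any(np.diff(d) <= 0):
            raise ValueError("densities must be strictly increasing")


def percentile_p(observed: float, null: np.ndarray) -> float:
    """Two-tailed permutation p from the percentile position of ``observed``
    in ``null`` (+1 correction, capped at 1). NaN null entries are dropped."""
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    n = len(null)
    if n == 0 or not np.isfinite(observed):
        return float("nan")
    hi = (1 + np.sum(null >= observed)) / (n + 1)
    lo = (1 + np.sum(null <= observed)) / (n + 1)
    return float(min(1.0, 2.0 * min(hi, lo)))


def _corr(Y: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(Y, rowvar=False)
    np.fill_diagonal(R, 0.0)
    return R


def measure_curves(Y: np.ndarray, grid: np.ndarray, measures: tuple[str, ...],
                   n_null: int = 20, seed: int = 0,
                   absolute: bool = False) -> dict[str, np.ndarray]:
    """Evaluate global measures of one group's network across the grid.

    ``Y`` is the (subjects x ROIs) residual matrix of one group. Returns
    one curve (array over densities) per requested measure.
    """
    R = _corr(Y)
    ei, ej = ranked_edges(R, absolute)
    n = R.shape[0]
    grid = np.asarray(grid, dtype=float)
    out = {m: np.full(len(grid), np.nan) for m in measures}
    need_sw = bool(_SW_MEASURES & set(measures))
    need_adj = need_sw or "C" in measures or "L" in measures
    for di, d in enumerate(grid):
        e = edge_count_for_density(float(d), n)
        if "Q" in measures:
            g = ig.Graph(n=n, edges=list(zip(ei[:e].tolist(), ej[:e].tolist())))
            memb = leiden_membership(g, seed=seed)
            out["Q"][di] = g.modularity(memb)
        if need_adj:
            A = np.zeros((n, n), dtype=np.int8)
            A[ei[:e], ej[:e]] = 1
            A = A | A.T
            _, C = clustering_coefficient(A)
            L = characteristic_path_length(A)
            if "C" in measures:
                out["C"][di] = C
            if "L" in measures:
                out["L"][di] = L
            if need_sw:
                ens = null_ensemble(A, n_null=n_null,
                                    seed=(seed * 1009 + di) % (2**31 - 1))
                C_null = np.mean([clustering_coefficient(H)[1] for H in ens])
                L_null = np.mean([characteristic_path_length(H) for H in ens])
                gamma = C / C_null if C_null > 0 else np.nan
                lam = L / L_null
                if "gamma" in measures:
                    out["gamma"][di] = gamma
                if "lambda" in measures:
                    out["lambda"][di] = lam
                if "sigma" in measures:
                    out["sigma"][di] = gamma / lam
    return out


def auc_summary(grid: np.ndarray, observed_diff: np.ndarray,
                null_diffs: np.ndarray) -> tuple[float, float]:
    """Trapezoidal integral of the difference curve over the grid and its
    permutation p-value."""
    grid = np.asarray(grid, dtype=float)
    observed_diff = np.asarray(observed_diff, dtype=float)
    null_diffs = np.asarray(null_diffs, dtype=float)
    if len(grid) < 2:
        raise ValueError("AUC needs a grid with >= 2 densities")
    if observed_diff.shape != grid.shape or null_diffs.shape[1] != len(grid):
        raise ValueError("curves and grid have mismatched lengths")
    stat = float(np.trapezoid(observed_diff, grid))
    null_stats = np.trapezoid(null_diffs, grid, axis=1)
    return stat, percentile_p(stat, null_stats)


def fda_summary(grid: np.ndarray, observed_diff: np.ndarray,
                null_diffs: np.ndarray) -> tuple[float, float]:
    """Functional summary: sum of the difference curve over grid points,
    with its permutation p-value. On a single-density grid this reduces to
    the pointwise difference."""
    grid = np.asarray(grid, dtype=float)
    observed_diff = np.asarray(observed_diff, dtype=float)
    null_diffs = np.asarray(null_diffs, dtype=float)
    if observed_diff.shape != grid.shape or null_diffs.shape[1] != len(grid):
        raise ValueError("curves and grid have mismatched lengths")
    stat = float(observed_diff.sum())
    return stat, percentile_p(stat, null_diffs.sum(axis=1))


@dataclass
class PermutationResult:
    """Per-density and summary inference for one global measure."""

    measure: str
    densities: np.ndarray
    curve_a: np.ndarray
    curve_b: np.ndarray
    observed: np.ndarray  # curve_a - curve_b
    ci_low: np.ndarray  # 2.5th percentile of the null differences
    ci_high: np.ndarray  # 97.5th percentile
    p_by_density: np.ndarray
    auc_stat: float
    auc_p: float
    fda_stat: float
    fda_p: float
    n_permutations: int
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.p_by_density < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "measure": self.measure, "density": self.densities,
            "group_a": self.curve_a, "group_b": self.curve_b,
            "difference": self.observed, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p_by_density,
            "significant": self.significant,
        })

    def to_dict(self) -> dict:
        d = self.to_frame().to_dict(orient="list")
        d.update(measure=self.measure, auc_stat=self.auc_stat,
                 auc_p=self.auc_p, fda_stat=self.fda_stat, fda_p=self.fda_p,
                 n_permutations=self.n_permutations, alpha=self.alpha)
        return d


def _split(residuals: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    groups = sorted(residuals["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    cols = roi_columns(residuals)
    Y = residuals[cols].to_numpy(dtype=float)
    labels = residuals["group"].to_numpy()
    return Y, labels, groups, cols


def permutation_test_global(residuals: pd.DataFrame,
                            config: PermutationConfig) -> dict[str, PermutationResult]:
    """Subject-relabeling permutation test of global measures across the
    density grid; one PermutationResult per measure."""
    config.validate()
    Y, labels, groups, _ = _split(residuals)
    grid = np.asarray(config.densities, dtype=float)
    mask_a = labels == groups[0]
    n_a = int(mask_a.sum())
    n = len(labels)

    def curves(idx, seed):
        return measure_curves(Y[idx], grid, config.measures,
                              n_null=config.n_null, seed=seed,
                              absolute=config.absolute)

    # both groups use the same measure seed so that algorithmic noise in
    # community detection is paired and cancels for identical inputs
    obs_a = curves(np.flatnonzero(mask_a), config.seed)
    obs_b = curves(np.flatnonzero(~mask_a), config.seed)

    rng = np.random.default_rng(config.seed)
    null_diffs = {m: np.empty((config.n_permutations, len(grid)))
                  for m in config.measures}
    for k in range(config.n_permutations):
        perm = rng.permutation(n)
        s = (config.seed * 2_000_003 + k) % (2**31 - 1)
        ca = curves(perm[:n_a], s)
        cb = curves(perm[n_a:], s)
        for m in config.measures:
            null_diffs[m][k] = ca[m] - cb[m]

    results = {}
    for m in config.measures:
        diff = obs_a[m] - obs_b[m]
        nd = null_diffs[m]
        p = np.array([percentile_p(diff[i], nd[:, i]) for i in range(len(grid))])
        ci_low = np.nanpercentile(nd, 2.5, axis=0)
        ci_high = np.nanpercentile(nd, 97.5, axis=0)
        if len(grid) >= 2:
            auc_stat, auc_p = auc_summary(grid, diff, nd)
        else:
            auc_stat, auc_p = float("nan"), float("nan")
        fda_stat, fda_p = fda_summary(grid, diff, nd)
        results[m] = PermutationResult(
            m, grid, obs_a[m], obs_b[m], diff, ci_low, ci_high, p,
            auc_stat, auc_p, fda_stat, fda_p, config.n_permutations,
            config.alpha)
    return results


def _betweenness_normalized(Y: np.ndarray, e: int, absolute: bool) -> np.ndarray:
    R = _corr(Y)
    ei, ej = ranked_edges(R, absolute)
    n = R.shape[0]
    g = ig.Graph(n=n, edges=list(zip(ei[:e].tolist(), ej[:e].tolist())))
    b = np.asarray(g.betweenness(), dtype=float)
    m = b.mean()
    return b / m if m != 0 else b


def reference_density(residuals: pd.DataFrame, grid: np.ndarray,
                      absolute: bool = False) -> float:
    """Smallest grid density at which both groups' networks are connected
    (falls back to the largest grid density if none qualifies)."""
    from .network import association_matrix, threshold_at_density
    groups = sorted(residuals["group"].unique())
    mats = [association_matrix(residuals, g) for g in groups]
    for d in np.asarray(grid, dtype=float):
        if all(threshold_at_density(R, float(d), absolute=absolute).is_connected()
               for R in mats):
            return float(d)
    return float(np.asarray(grid)[-1])


@dataclass
class NodalComparison:
    """Per-node permutation comparison of normalized betweenness."""

    frame: pd.DataFrame  # node, difference, ci_low, ci_high, p, significant
    density: float
    n_permutations: int
    alpha: float

    @property
    def significant_nodes(self) -> list[str]:
        return list(self.frame.loc[self.frame["significant"], "node"])


def permutation_test_nodal(residuals: pd.DataFrame, config: PermutationConfig,
                           density: float | None = None) -> NodalComparison:
    """Per-node normalized-betweenness comparison at a reference density
    (default: the minimum grid density at which both observed group
    networks are connected)."""
    config.validate()
    Y, labels, groups, cols = _split(residuals)
    grid = np.asarray(config.densities, dtype=float)
    if density is None:
        density = reference_density(residuals, grid, config.absolute)
    n_nodes = Y.shape[1]
    e = edge_count_for_density(float(density), n_nodes)
    mask_a = labels == groups[0]
    n_a = int(mask_a.sum())
    n = len(labels)

    obs = (_betweenness_normalized(Y[mask_a], e, config.absolute)
           - _betweenness_normalized(Y[~mask_a], e, config.absolute))
    rng = np.random.default_rng(config.seed)
    null = np.empty((config.n_permutations, n_nodes))
    for k in range(config.n_permutations):
        perm = rng.permutation(n)
        null[k] = (_betweenness_normalized(Y[perm[:n_a]], e, config.absolute)
                   - _betweenness_normalized(Y[perm[n_a:]], e, config.absolute))

    p = np.array([percentile_p(obs[j], null[:, j]) for j in range(n_nodes)])
    frame = pd.DataFrame({
        "node": cols, "difference": obs,
        "ci_low": np.nanpercentile(null, 2.5, axis=0),
        "ci_high": np.nanpercentile(null, 97.5, axis=0),
        "p": p, "significant": p < config.alpha,
    })
    return NodalComparison(frame, float(density), config.n_permutations,
                           config.alpha)


@dataclass
class HubComparison:
    shared: list[str]
    only_a: list[str]
    only_b: list[str]

    def to_dict(self) -> dict:
        return {"shared": self.shared, "only_a": self.only_a,
                "only_b": self.only_b, "n_shared": len(self.shared),
                "n_only_a": len(self.only_a), "n_only_b": len(self.only_b)}


def compare_hubs(hubs_a: HubSet, hubs_b: HubSet) -> HubComparison:
    """Shared and group-unique hubs (order follows the node universe)."""
    if set(hubs_a.universe) != set(hubs_b.universe):
        raise ValueError("hub sets come from different node-label universes")
    sa, sb = set(hubs_a.members), set(hubs_b.members)
    order = {lab: i for i, lab in enumerate(hubs_a.universe)}
    key = order.get
    return HubComparison(sorted(sa & sb, key=key), sorted(sa - sb, key=key),
                         sorted(sb - sa, key=key))
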