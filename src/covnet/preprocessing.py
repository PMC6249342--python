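"""Cohort quality control and confound correction.

Two steps precede network construction:

1. **Sample homogeneity check** — each subject's ROI-volume vector is
   correlated with every other subject's; subjects whose mean inter-subject
   correlation falls more than 2 SD below the cohort mean are flagged as
   outliers and excluded. This is a table-level re-expression of the usual
   image-space covariance screen.
2. **Residualization** — per ROI, ordinary least squares of volume on an
   intercept plus nuisance covariates (typically age and total brain
   volume); the residuals are the "corrected" volumes that enter the
   covariance network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import roi_columns


@dataclass
class QCReport:
    """Outcome of the homogeneity screen."""

    scores: pd.Series  # mean inter-subject correlation, indexed by subject_id
    flagged: list[str]  # subject_ids below the threshold
    threshold: float  # mean(scores) - n_sd * SD(scores)
    n_sd: float
    flag_counts_by_group: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scores": self.scores.to_dict(),
            "flagged": self.flagged,
            "threshold": self.threshold,
            "n_sd": self.n_sd,
            "flag_counts_by_group": self.flag_counts_by_group,
        }


def homogeneity_check(table: pd.DataFrame, n_sd: float = 2.0) -> QCReport:
    """Score each subject's similarity to the rest of the cohort and flag
    outliers.

    score_i = mean Pearson correlation of subject i's ROI-volume vector with
    every other subject's vector; a subject is flagged when
    score_i < mean(scores) - n_sd * SD(scores). Flags are invariant to
    subject ordering.
    """
    if len(table) < 4:
        raise ValueError("homogeneity check needs at least 4 subjects")
    cols = roi_columns(table)
    vols = table[cols].to_numpy(dtype=float)
    sds = vols.std(axis=1)
    if (sds == 0).any():
        bad = table["subject_id"].iloc[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"subject {bad!r} has a constant volume vector; "
                         "correlation is undefined")
    corr = np.corrcoef(vols)
    n = len(table)
    scores = (corr.sum(axis=1) - 1.0) / (n - 1)
    score_ser = pd.Series(scores, index=table["subject_id"].to_numpy())
    sd = scores.std(ddof=1)
    threshold = scores.mean() - n_sd * sd
    if sd == 0:
        flagged_mask = np.zeros(n, dtype=bool)
    else:
        flagged_mask = scores < threshold
    flagged = list(table["subject_id"].to_numpy()[flagged_mask])
    counts = (
        table.loc[flagged_mask, "group"].value_counts().to_dict()
        if "group" in table.columns else {}
    )
    counts = {str(k): int(v) for k, v in counts.items()}
    return QCReport(score_ser, flagged, float(threshold), n_sd, counts)


def drop_flagged(table: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """Remove flagged subjects (QC precedes confound correction)."""
    keep = ~table["subject_id"].isin(report.flagged)
    return table.loc[keep].reset_index(drop=True)


def _design_matrix(table: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    n = len(table)
    X = np.ones((n, len(covariates) + 1))
    for k, cov in enumerate(covariates, start=1):
        if cov not in table.columns:
            raise ValueError(f"covariate column {cov!r} not found in table")
        col = table[cov].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {cov!r} is constant; design matrix "
                             "would be rank-deficient")
        X[:, k] = col
    # locate the first covariate that adds no rank (collinearity)
    for k in range(2, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :k]) < k:
            raise ValueError(f"covariate {covariates[k - 2]!r} is collinear "
                             "with earlier columns")
    return X


def residualize(table: pd.DataFrame, covariates: list[str] | tuple[str, ...] = ("age", "tbv"),
                mode: str = "pooled") -> pd.DataFrame:
    """OLS-residualize every ROI column on an intercept plus ``covariates``.

    Parameters
    ----------
    mode : {"pooled", "per_group"}
        "pooled" fits one regression per ROI across all retained subjects
        (the default correction model); "per_group" fits separately within
        each group.

    Returns a table with subject_id, group, and one residual column per
    ROI. Residuals are exactly orthogonal to each covariate and have zero
    mean within each regression sample.
    """
    covariates = list(covariates)
    if mode not in ("pooled", "per_group"):
        raise ValueError(f"unknown mode {mode!r}")
    cols = roi_columns(table)
    cols = [c for c in cols if c not in covariates]

    def _fit(sub: pd.DataFrame) -> np.ndarray:
        if len(sub) <= len(covariates) + 1:
            raise ValueError("need more subjects than covariates + 1")
        X = _design_matrix(sub, covariates)
        Y = sub[cols].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return Y - X @ beta

    out = table[["subject_id", "group"]].copy().reset_index(drop=True)
    if mode == "pooled":
        resid = _fit(table)
    else:
        resid = np.empty((len(table), len(cols)))
        tbl = table.reset_index(drop=True)
        for g in tbl["group"].unique():
            mask = (tbl["group"] == g).to_numpy()
            resid[mask] = _fit(tbl.loc[mask])
    out[cols] = resid
    return out
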