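"""Synthetic two-group cohorts with planted modular covariance structure.

Real structural-covariance studies start from a subject x ROI table of
regional gray-matter volumes. This module generates such tables from a
latent-factor model with a planted module partition, so that recovery of the
partition and of between-group differences can be tested against ground
truth.

Generative model, per subject *i* in group *g* and ROI *j* with module
``m(j)``::

    v_ij = mu_j + w_g * f_{i, m(j)} + beta_age * age_i + beta_tbv * tbv_i + eps_ij

where ``f`` are i.i.d. standard-normal latent module factors (one draw per
subject per module), ``eps`` is Gaussian noise with SD ``noise_sd``, and
``w_g`` is the group's within-module loading. After residualizing out the
confounds, ROIs sharing a module correlate at w_g^2 / (w_g^2 + noise_sd^2)
in expectation, while ROIs in different modules are uncorrelated — exactly
the block structure a covariance network detects. A larger loading gives
stronger within-module correlation, hence denser within-module edges after
thresholding and higher modularity Q.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import aal90_labels

GROUPS = ("A", "B")


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study conditions of a typical two-group
    structural-covariance comparison: ~30 subjects per group, 90 AAL ROIs,
    four latent modules, an elderly age range and realistic total brain
    volumes, with group B carrying stronger within-module covariance.
    """

    n_subjects_per_group: int = 30
    n_rois: int = 90
    n_modules: int = 4
    #: ROI index (0-based) -> module id; default: contiguous, near-equal blocks
    module_assignment: dict[int, int] | None = None
    within_loading_by_group: tuple[float, float] = (0.45, 0.75)
    noise_sd: float = 1.0
    #: per-year slope of ROI volume on age (mild atrophy)
    age_effect: float = -0.02
    #: slope of ROI volume on total brain volume (scaling with head size)
    tbv_effect: float = 0.005
    age_range: tuple[float, float] = (55.0, 82.0)
    tbv_range: tuple[float, float] = (1100.0, 1600.0)
    #: range of per-ROI baseline mean volumes mu_j (volume units); real
    #: regional GM volumes differ widely between regions, which is what
    #: makes subjects' volume profiles mutually correlated and the
    #: homogeneity screen meaningful
    baseline_range: tuple[float, float] = (4.0, 16.0)
    n_outliers: int = 0
    outlier_magnitude: float = 8.0
    seed: int = 0

    def resolved_modules(self) -> np.ndarray:
        """Module id per ROI as an int array of length n_rois."""
        if self.module_assignment is None:
            chunks = np.array_split(np.arange(self.n_rois), self.n_modules)
            return np.concatenate(
                [np.full(len(chunk), m) for m, chunk in enumerate(chunks)]
            )
        out = np.empty(self.n_rois, dtype=int)
        out.fill(-1)
        for roi, mod in self.module_assignment.items():
            out[roi] = mod
        if (out < 0).any():
            missing = int(np.flatnonzero(out < 0)[0])
            raise ValueError(f"module_assignment does not cover ROI {missing}")
        return out

    def validate(self) -> None:
        if self.n_subjects_per_group < 3:
            raise ValueError("n_subjects_per_group must be >= 3 (Pearson r needs >= 3 points)")
        if self.n_rois < 1:
            raise ValueError("n_rois must be positive")
        if not 1 <= self.n_modules <= self.n_rois:
            raise ValueError("n_modules must be in [1, n_rois]")
        for w in self.within_loading_by_group:
            if not 0.0 <= w < 1.0:
                raise ValueError("within_loading_by_group entries must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be non-negative")
        mods = self.resolved_modules()
        if len(np.unique(mods)) > self.n_modules:
            raise ValueError("module_assignment uses more modules than n_modules")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    module_assignment: np.ndarray
    within_loading_by_group: tuple[float, float]
    age_effect: float
    tbv_effect: float
    outlier_subjects: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_assignment": self.module_assignment.tolist(),
            "within_loading_by_group": list(self.within_loading_by_group),
            "age_effect": self.age_effect,
            "tbv_effect": self.tbv_effect,
            "outlier_subjects": self.outlier_subjects,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def roi_columns(table: pd.DataFrame) -> list[str]:
    """Names of the ROI volume columns (everything beyond the covariates)."""
    meta = {"subject_id", "group", "age", "tbv"}
    return [c for c in table.columns if c not in meta]


def _roi_names(n_rois: int) -> list[str]:
    if n_rois == 90:
        return aal90_labels()
    return [f"ROI_{i + 1:03d}" for i in range(n_rois)]


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a two-group cohort table plus its ground truth.

    Deterministic for a fixed spec (single RNG stream seeded with
    ``spec.seed``). Volumes are floored at 0 (gray-matter volumes are
    non-negative).
    """
    spec.validate()
    modules = spec.resolved_modules()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects_per_group, spec.n_rois
    names = _roi_names(p)

    baseline = rng.uniform(*spec.baseline_range, size=p)  # mu_j, shared by groups
    rows = []
    for g, (label, w) in enumerate(zip(GROUPS, spec.within_loading_by_group)):
        age = rng.uniform(*spec.age_range, size=n)
        tbv = rng.uniform(*spec.tbv_range, size=n)
        factors = rng.standard_normal((n, spec.n_modules))
        eps = rng.standard_normal((n, p)) * spec.noise_sd
        vols = (
            baseline[None, :]
            + w * factors[:, modules]
            + spec.age_effect * age[:, None]
            + spec.tbv_effect * tbv[:, None]
            + eps
        )
        np.maximum(vols, 0.0, out=vols)
        for i in range(n):
            rows.append(
                {"subject_id": f"{label}{i + 1:03d}", "group": label,
                 "age": age[i], "tbv": tbv[i],
                 **dict(zip(names, vols[i]))}
            )
    table = pd.DataFrame(rows)

    outliers: list[str] = []
    if spec.n_outliers:
        picks = rng.choice(len(table), size=spec.n_outliers, replace=False)
        for idx in np.sort(picks):
            table = inject_outlier(table, int(idx), spec.outlier_magnitude)
            outliers.append(table.loc[idx, "subject_id"])

    truth = GroundTruth(modules, tuple(spec.within_loading_by_group),
                        spec.age_effect, spec.tbv_effect, outliers)
    return table, truth


def inject_outlier(table: pd.DataFrame, subject: int | str,
                   magnitude: float) -> pd.DataFrame:
    """Return a copy of ``table`` with one subject perturbed into an outlier.

    The subject's ROI vector gains ``magnitude`` cohort-SDs of a random-sign
    pattern (pattern fixed by the subject's row index, so the operation is
    deterministic and two different outliers get uncorrelated patterns).
    ``magnitude = 0`` leaves the table unchanged.
    """
    if isinstance(subject, str):
        hits = np.flatnonzero(table["subject_id"].to_numpy() == subject)
        if len(hits) == 0:
            raise KeyError(f"unknown subject_id {subject!r}")
        idx = int(hits[0])
    else:
        idx = int(subject)
        if not 0 <= idx < len(table):
            raise KeyError(f"subject index {idx} out of range (n={len(table)})")

    out = table.copy()
    cols = roi_columns(table)
    vols = table[cols].to_numpy(dtype=float)
    sd = vols.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    pattern_rng = np.random.default_rng(1_000_003 + idx)
    signs = pattern_rng.choice([-1.0, 1.0], size=len(cols))
    out.loc[out.index[idx], cols] = np.maximum(
        vols[idx] + magnitude * sd * signs, 0.0
    )
    return out
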