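"""Cohort table I/O, run configuration, and provenance metadata."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import aal90_labels
from .network import AssociationMatrix, density_grid


def read_cohort(path: str | Path, require_atlas: bool = True) -> pd.DataFrame:
    """Read and validate a cohort table (CSV or TSV by extension).

    Required columns: subject_id, group, plus the covariates and ROI volume
    columns. With ``require_atlas`` (default) the 90 AAL ROI columns must
    all be present; missing ones are reported by name.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep)
    for col in ("subject_id", "group"):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    if require_atlas:
        missing = [lab for lab in aal90_labels() if lab not in table.columns]
        if missing:
            raise ValueError(
                f"cohort table is missing {len(missing)} atlas ROI columns: "
                + ", ".join(missing[:10])
                + ("..." if len(missing) > 10 else ""))
        bad = [lab for lab in aal90_labels()
               if not np.issubdtype(table[lab].dtype, np.number)]
        if bad:
            raise ValueError(f"non-numeric volume column {bad[0]!r}")
        if table[aal90_labels()].isna().any().any():
            na_col = table[aal90_labels()].isna().any().idxmax()
            row = int(table[na_col].isna().idxmax())
            raise ValueError(f"missing volume in column {na_col!r}, row {row}")
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.to_csv(path, sep=sep, index=False)


def write_matrix_tsv(R: AssociationMatrix | np.ndarray, labels: list[str],
                     path: str | Path) -> None:
    """Write a square matrix as TSV with node-label header and index."""
    values = R.values if isinstance(R, AssociationMatrix) else np.asarray(R)
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> AssociationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return AssociationMatrix(frame.to_numpy(dtype=float), list(frame.columns))


def write_edge_list(R: AssociationMatrix, adjacency: np.ndarray,
                    path: str | Path) -> None:
    """Edges of a binary graph as 3-column TSV (node_i, node_j, r)."""
    ei, ej = np.nonzero(np.triu(adjacency, k=1))
    rows = [(R.node_labels[i], R.node_labels[j], R.values[i, j])
            for i, j in zip(ei, ej)]
    pd.DataFrame(rows, columns=["node_i", "node_j", "r"]).to_csv(
        path, sep="\t", index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration. Defaults follow standard
    covariance-network practice: density grid 0.10-0.50 in 0.02 steps,
    1,000 permutations, mean + 2 SD hub rule, alpha 0.05."""

    cohort_path: str = ""
    out_dir: str = "covnet_results"
    covariates: tuple[str, ...] = ("age", "tbv")
    residual_mode: str = "pooled"  # or "per_group"
    qc_sd: float = 2.0
    density_min: float = 0.10
    density_max: float = 0.50
    density_step: float = 0.02
    n_permutations: int = 1000
    n_null: int = 20
    measures: tuple[str, ...] = ("Q",)
    alpha: float = 0.05
    hub_sd: float = 2.0
    thresholding: str = "signed"  # or "absolute"
    nodal_density: float | None = None
    seed: int = 0

    def densities(self) -> np.ndarray:
        return density_grid(self.density_min, self.density_max,
                            self.density_step)

    @property
    def absolute(self) -> bool:
        return self.thresholding == "absolute"

    def validate(self) -> None:
        if self.thresholding not in ("signed", "absolute"):
            raise ValueError(f"unknown thresholding {self.thresholding!r}")
        if self.residual_mode not in ("pooled", "per_group"):
            raise ValueError(f"unknown residual_mode {self.residual_mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.qc_sd <= 0 or self.hub_sd <= 0:
            raise ValueError("SD thresholds must be positive")
        self.densities()  # raises on a bad grid

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for tup_field in ("covariates", "measures"):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        d["measures"] = list(self.measures)
        return d

    def provenance(self) -> dict:
        """Metadata embedded in every results file: the full config, its
        hash, the expanded density grid, seeds and software version."""
        cfg = self.to_dict()
        blob = json.dumps(cfg, sort_keys=True).encode()
        grid = self.densities()
        return {
            "package": "covnet",
            "version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "densities": grid.tolist(),
            "n_densities": int(len(grid)),
            "n_permutations": self.n_permutations,
            "hub_rule": f"betweenness >= mean + {self.hub_sd} * SD",
            "hub_sd": self.hub_sd,
            "seed": self.seed,
        }


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
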