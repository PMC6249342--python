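"""Minimal plotting helpers (density curves and permutation CI bands)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .compare import PermutationResult  # noqa: E402


def plot_metric_curves(curves, measure: str, path: str | Path) -> None:
    """One line per group of ``measure`` across the density grid.

    ``curves`` is the tidy global-metrics frame produced by the pipeline
    (columns group, density, and one column per measure).
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in curves.groupby("group"):
        ax.plot(sub["density"], sub[measure], marker="o", label=str(g))
    ax.set_xlabel("network density D")
    ax.set_ylabel(measure)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_permutation_band(result: PermutationResult, path: str | Path) -> None:
    """Observed group difference with the 95% permutation CI band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(result.densities, result.ci_low, result.ci_high,
                    alpha=0.3, label="95% permutation CI")
    ax.plot(result.densities, result.observed, "k+", label="observed diff")
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("network density D")
    ax.set_ylabel(f"{result.measure} difference (A - B)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
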