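"""Report serialization: TSV tables, JSON summaries and optional plots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    CrossValResult,
    PermutationResult,
    PopularityTable,
    SweepResult,
    sorted_popularity_curve,
)

__all__ = [
    "popularity_frame",
    "sweep_frame",
    "crossval_frame",
    "permutation_summary",
    "write_tsv",
    "write_json",
    "plot_popularity",
    "plot_crossval_histogram",
    "plot_fidelity",
]


def popularity_frame(table: PopularityTable) -> pd.DataFrame:
    curve, cliff = sorted_popularity_curve(table)
    frame = pd.DataFrame(curve, columns=["name", "count"])
    frame.insert(0, "rank", np.arange(1, len(curve) + 1))
    frame.attrs["cliff_rank"] = cliff
    return frame


def sweep_frame(result: SweepResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "L": result.limits,
            "metric": result.final_metrics,
            "empirical_p": result.empirical_ps,
            "n_selected": result.n_selected,
        }
    )


def crossval_frame(result: CrossValResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": np.arange(1, result.trials + 1),
            "holdout_metric": result.holdout_metrics,
            "train_metric": result.train_metrics,
        }
    )


def permutation_summary(result: PermutationResult) -> dict:
    return {
        "true_metric": result.true_metric,
        "E": result.E,
        "D": result.D,
        "empirical_p": result.empirical_p,
        "permuted_metric_mean": float(np.mean(result.permuted_metrics)),
        "permuted_metric_sd": float(np.std(result.permuted_metrics, ddof=1))
        if result.D > 1
        else 0.0,
    }


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _agg_axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_popularity(table: PopularityTable, path: str | Path, top: int = 30) -> None:
    """Bar chart of the sorted selection counts with the cliff marked."""
    plt = _agg_axes()
    curve, cliff = sorted_popularity_curve(table)
    curve = curve[:top]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(curve)), [c for _, c in curve], color="steelblue")
    ax.axvline(cliff - 0.5, color="firebrick", linestyle="--", label=f"cliff at {cliff}")
    ax.set_xticks(range(len(curve)))
    ax.set_xticklabels([n for n, _ in curve], rotation=90, fontsize=6)
    ax.set_ylabel(f"selections in {table.trials} trials")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_crossval_histogram(
    true_result: CrossValResult, perm_result: CrossValResult, path: str | Path
) -> None:
    """Overlaid histograms of holdout metrics, observed vs permuted-target."""
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(-1, 1, 41)
    ax.hist(
        true_result.holdout_metrics[~np.isnan(true_result.holdout_metrics)],
        bins=bins, alpha=0.6, label="TRUE", color="steelblue",
    )
    ax.hist(
        perm_result.holdout_metrics[~np.isnan(perm_result.holdout_metrics)],
        bins=bins, alpha=0.6, label="PERM", color="grey",
    )
    ax.set_xlabel("holdout metric")
    ax.set_ylabel("trials")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fidelity(pairs: np.ndarray, r: float, path: str | Path) -> None:
    """Scatter of exact vs coarse dot products."""
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs[:, 0], pairs[:, 1], s=12, alpha=0.7)
    ax.set_xlabel("A · B")
    ax.set_ylabel("coarsen(A) · B")
    ax.set_title(f"r = {r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
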