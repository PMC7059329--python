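"""Plot helpers for the selection trace, residual curves and importances."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_sa_trace", "plot_residual_profiles", "plot_importance"]


def _save(fig, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_sa_trace(trace, path) -> None:
    """Iteration vs mean internal/external accuracy of the subset search."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trace.mean_internal().index, trace.mean_internal().values,
            label="internal", lw=1)
    ax.plot(trace.mean_external().index, trace.mean_external().values,
            label="external", lw=1)
    best = trace.mean_external().idxmax()
    ax.axvline(best, color="grey", ls="--", lw=0.8,
               label=f"best iteration {best}")
    ax.set_xlabel("iteration")
    ax.set_ylabel("mean accuracy")
    ax.legend()
    _save(fig, path)


def plot_residual_profiles(profiles: dict, path) -> None:
    """Overlayed cross-entropy exceedance curves, one per model."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, profile in profiles.items():
        ax.plot(profile["threshold"], profile["fraction_above"], label=name)
    ax.set_xlabel("binary cross entropy")
    ax.set_ylabel("fraction of compounds above")
    ax.legend()
    _save(fig, path)


def plot_importance(importance, path, top_n: int = 10) -> None:
    """Horizontal bar plot of the top features with the baseline loss noted."""
    top = importance.head(top_n).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(top) + 1.5))
    ax.barh(top["feature"], top["importance_mean"],
            xerr=top["importance_sd"], color="#4878a8")
    baseline = float(importance["baseline_loss"].iloc[0])
    ax.set_xlabel(f"loss increase (baseline cross entropy {baseline:.3f})")
    _save(fig, path)
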