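"""Small plotting helpers for recovery matrices and effect sweeps."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_confusion", "plot_sweep"]


def plot_confusion(matrix: pd.DataFrame, title: str = "", path=None):
    """Heatmap of a model-recovery confusion matrix (rows sum to 1)."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(len(matrix.index)):
        for j in range(len(matrix.columns)):
            val = matrix.iat[i, j]
            if np.isfinite(val):
                ax.text(j, i, f"{val:.2f}", ha="center", va="center",
                        color="w" if val < 0.6 else "k", fontsize=8)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_sweep(sweep: pd.DataFrame, path=None):
    """Bar panels of the four effects across the sweep nodes (with SEM bars)."""
    effects = ["performance_effect", "confidence_effect",
               "confidence_value_effect", "consistency_effect"]
    fig, axes = plt.subplots(2, 2, figsize=(10, 6))
    x = np.arange(len(sweep))
    for ax, eff in zip(axes.ravel(), effects):
        ax.bar(x, sweep[eff], yerr=sweep[f"{eff}_sem"], color="tab:blue",
               error_kw={"lw": 0.8})
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(eff.replace("_", " "))
        ax.set_xlabel("sweep node")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
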