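"""Simple figure exports (stacked-area process dynamics, concordance heatmap)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

_CATEGORY_COLORS = {
    "lipid": "#e6b422",
    "inflammation": "#c0392b",
    "fibrosis": "#2980b9",
    "other": "#95a5a6",
}


def plot_process_dynamics(dynamics: pd.DataFrame, path: str | Path) -> None:
    """Stacked-area chart of category shares over time, one panel per tissue."""
    tissues = sorted(dynamics["tissue"].unique())
    fig, axes = plt.subplots(1, len(tissues), figsize=(5 * len(tissues), 3.2), squeeze=False)
    for ax, tissue in zip(axes[0], tissues):
        sub = dynamics[dynamics["tissue"] == tissue]
        times = sorted(sub["time_weeks"].unique())
        cats = [c for c in _CATEGORY_COLORS if c in set(sub["category"])]
        shares = [
            [
                float(
                    sub[(sub["category"] == c) & (sub["time_weeks"] == t)]["share"].iloc[0]
                )
                for t in times
            ]
            for c in cats
        ]
        ax.stackplot(times, shares, labels=cats, colors=[_CATEGORY_COLORS[c] for c in cats])
        ax.set_title(tissue)
        ax.set_xlabel("weeks on diet")
        ax.set_ylabel("share of top pathways")
        ax.set_ylim(0, 1)
    axes[0][-1].legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_concordance_heatmap(table: pd.DataFrame, path: str | Path) -> None:
    """One-column heatmap of second-study log2FC per regulator (blue=down, red=up)."""
    genes = table["gene"].tolist()
    values = table["log2fc_study2"].to_numpy(dtype=float)[:, None]
    vmax = np.nanmax(np.abs(values)) or 1.0
    fig, ax = plt.subplots(figsize=(2.2, 0.3 * max(len(genes), 4) + 1))
    im = ax.imshow(values, cmap="bwr", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    ax.set_xticks([0], ["log2FC"], fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
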