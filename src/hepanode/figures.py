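"""Publication-style figures (headless-safe, optional)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def confidence_histograms(
    reader_ordinals: dict[str, np.ndarray],
    model_ordinals: dict[str, np.ndarray],
    path: str | Path,
) -> None:
    """Per-rater histograms over the 10-point scale, low-confidence zone
    (4-7) outlined with dashed lines."""
    panels = {**reader_ordinals, **model_ordinals}
    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3), sharey=True)
    if len(panels) == 1:
        axes = [axes]
    for ax, (name, ords) in zip(axes, panels.items()):
        ax.hist(ords, bins=np.arange(0.5, 11.5), color="#4878d0", edgecolor="black")
        ax.axvline(3.5, ls="--", c="k")
        ax.axvline(7.5, ls="--", c="k")
        ax.set_title(name)
        ax.set_xlabel("confidence / probability ordinal")
    axes[0].set_ylabel("nodules")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def feature_boxplots(lesion_features: pd.DataFrame, labels: dict[str, int], path: str | Path) -> None:
    """Box plots of each physical feature by class and by probability cluster."""
    feature_cols = [c for c in lesion_features.columns if c != "cluster"]
    y = lesion_features.index.map(labels)
    fig, axes = plt.subplots(2, len(feature_cols), figsize=(3.2 * len(feature_cols), 6))
    for j, name in enumerate(feature_cols):
        ax = axes[0, j]
        ax.boxplot(
            [lesion_features.loc[y == 0, name], lesion_features.loc[y == 1, name]],
            tick_labels=["benign", "malignant"],
        )
        ax.set_title(name)
        ax = axes[1, j]
        groups = sorted(lesion_features["cluster"].unique())
        ax.boxplot(
            [lesion_features.loc[lesion_features["cluster"] == g, name] for g in groups],
            tick_labels=[str(g) for g in groups],
        )
        ax.set_xlabel("probability cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def tsne_scatter(coords: np.ndarray, labels: np.ndarray, path: str | Path) -> None:
    """t-SNE scatter colored by reference-standard class."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, color, name in [(0, "#1f77b4", "benign"), (1, "#d62728", "malignant")]:
        sel = labels == cls
        ax.scatter(coords[sel, 0], coords[sel, 1], s=12, c=color, label=name, alpha=0.7)
    ax.legend()
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
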