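"""Basic figure output: correlation heatmap with significance mask and
PC1-PC2 scatter with 1-SD strain ellipses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .multivar import CorrelationMatrix, EllipseSpec


def correlation_heatmap(corr: CorrelationMatrix, path, title: str = "") -> None:
    """Heatmap of Pearson r; nonsignificant cells (p > alpha) carry an 'X'."""
    k = len(corr.traits)
    fig, ax = plt.subplots(figsize=(0.45 * k + 2, 0.45 * k + 2))
    im = ax.imshow(corr.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(k), corr.traits, rotation=90, fontsize=7)
    ax.set_yticks(range(k), corr.traits, fontsize=7)
    mask = corr.mask.to_numpy()
    for i in range(k):
        for j in range(k):
            if mask[i, j]:
                ax.text(j, i, "X", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_scatter(
    scores: pd.DataFrame,
    groups,
    ellipses: list[EllipseSpec] | None,
    path,
    title: str = "",
) -> None:
    """PC1-PC2 scatter colored by group with optional 1-SD normal ellipses."""
    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("tab10")
    for i, g in enumerate(pd.unique(groups)):
        pts = scores.loc[groups == g, ["PC1", "PC2"]]
        marker = "x" if g == "DO" else "o"
        ax.scatter(pts["PC1"], pts["PC2"], s=14, label=str(g),
                   color=cmap(i % 10), marker=marker, alpha=0.8)
    for i, e in enumerate(ellipses or []):
        if e.degenerate:
            continue
        t = np.linspace(0, 2 * np.pi, 100)
        xy = np.stack([e.axes[0] * np.cos(t), e.axes[1] * np.sin(t)])
        a = np.radians(e.angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        xy = rot @ xy
        ax.plot(xy[0] + e.center[0], xy[1] + e.center[1], lw=1, color=cmap(i % 10))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7, ncol=2)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
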