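"""Optional matplotlib renderings: correlogram and clustered heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .qpcr import CorrelationResult, ExpressionMatrix, heatmap_order


def plot_correlogram(result: CorrelationResult, path: str | Path) -> None:
    """Mixed correlogram: circles sized by |rho| above the diagonal, values below."""
    rho = result.rho
    genes = list(rho.index)
    n = len(genes)
    fig, ax = plt.subplots(figsize=(0.6 * n + 2, 0.6 * n + 2))
    cmap = plt.get_cmap("RdBu")
    for i in range(n):
        for j in range(n):
            r = rho.iat[i, j]
            if np.isnan(r):
                continue
            color = cmap(0.5 * (r + 1))
            if j > i:
                ax.scatter(j, n - 1 - i, s=600 * abs(r) + 10, c=[color], edgecolors="gray")
            elif j < i:
                ax.text(j, n - 1 - i, f"{r:.2f}", ha="center", va="center", fontsize=8)
    ax.set_xticks(range(n), genes, rotation=90)
    ax.set_yticks(range(n), genes[::-1])
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(-0.5, n - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(expr: ExpressionMatrix, path: str | Path) -> None:
    """Clustered expression heatmap (rows = genes, columns = cells)."""
    row_order, col_order, _, _ = heatmap_order(expr)
    data = expr.masked(missing=False).loc[row_order, col_order]
    fig, ax = plt.subplots(figsize=(0.25 * data.shape[1] + 2, 0.35 * data.shape[0] + 2))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(row_order)), row_order)
    ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="normalized Log2ex")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
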