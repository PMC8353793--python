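"""Minimal plotting helpers: signature heatmap and MDS scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_signature_heatmap(matrix: pd.DataFrame, path=None, title="Disease-modifying signature"):
    """Two-column fold-change heatmap (disease vs treated), diverging palette."""
    fig, ax = plt.subplots(figsize=(4, max(3, 0.12 * len(matrix))))
    lim = max(abs(matrix.to_numpy()).max(), 1e-6)
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdYlGn", vmin=-lim, vmax=lim)
    ax.set_xticks([0, 1], ["disease", "treated"])
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=5)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_mds(coords: pd.DataFrame, samples: pd.DataFrame | None = None, path=None):
    """Scatter of the first two MDS dimensions, coloured by genotype if known."""
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = None
    if samples is not None:
        palette = {"healthy": "tab:blue", "c9": "tab:red"}
        genotype = samples.set_index("sample_id").loc[coords.index, "genotype"]
        colors = [palette.get(g, "gray") for g in genotype]
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], c=colors)
    for sid, row in coords.iterrows():
        ax.annotate(sid, (row.iloc[0], row.iloc[1]), fontsize=5)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.set_title("Sample MDS (log-CPM distances)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
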