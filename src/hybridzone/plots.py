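"""Figures: windowed-FST Manhattan track, AIM ancestry painting, PCA scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan(windows, regions: pd.DataFrame | None, path, window_size: int = 50_000) -> None:
    """Mean FST per window along concatenated arms, shaded annotated regions."""
    frames = pd.DataFrame(
        [
            (w.chrom, w.start, w.end, w.mean_fst)
            for w in windows
            if w.mean_fst is not None
        ],
        columns=["chrom", "start", "end", "mean_fst"],
    )
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    offsets = {}
    for chrom, sub in frames.groupby("chrom", sort=False):
        offsets[chrom] = offset
        mid = (sub["start"] + sub["end"]) / 2
        ax.scatter(mid + offset, sub["mean_fst"], s=4, label=chrom)
        offset += sub["end"].max() + window_size
    if regions is not None:
        for _, r in regions.iterrows():
            if r["chrom"] in offsets:
                o = offsets[r["chrom"]]
                ax.axvspan(r["start"] + o, r["end"] + o, color="grey", alpha=0.2)
    ax.set_xlabel("genome position (arms concatenated)")
    ax.set_ylabel("mean $F_{ST}$ (50 kb windows)")
    ax.legend(fontsize=7, ncol=5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ancestry_painting(scores: pd.DataFrame, positions: dict[str, int], path) -> None:
    """Per-individual track of 0 / 0.5 / 1 AIM scores against genome position."""
    fig, ax = plt.subplots(figsize=(10, 0.25 * len(scores) + 1.5))
    cmap = {0.0: "#d62728", 0.5: "#9467bd", 1.0: "#2ca02c"}
    pos = np.array([positions[c] for c in scores.columns])
    for i, (ind, row) in enumerate(scores.iterrows()):
        vals = row.to_numpy(dtype=float)
        for v, colour in cmap.items():
            sel = vals == v
            ax.scatter(pos[sel], np.full(sel.sum(), i), s=6, color=colour, marker="|")
    ax.set_yticks(range(len(scores)))
    ax.set_yticklabels(scores.index, fontsize=6)
    ax.set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_scatter(coords: pd.DataFrame, groups: pd.Series | None, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    if groups is None:
        ax.scatter(coords["PC1"], coords["PC2"], s=12)
    else:
        for g in pd.unique(groups):
            sel = (groups == g).to_numpy()
            ax.scatter(coords["PC1"][sel], coords["PC2"][sel], s=12, label=str(g))
        ax.legend(fontsize=8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
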