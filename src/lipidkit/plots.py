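"""Optional matplotlib views of pipeline artifacts (volcano, curves, heatmap, PCA)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_volcano", "plot_fc_curves", "plot_zscore_heatmap", "plot_pca"]

PathLike = Union[str, Path]


def plot_volcano(differential: pd.DataFrame, path: PathLike, fdr_threshold: float = 0.05) -> None:
    contrasts = list(differential["contrast"].unique())
    fig, axes = plt.subplots(1, max(len(contrasts), 1), figsize=(4 * max(len(contrasts), 1), 4), squeeze=False)
    for ax, contrast in zip(axes[0], contrasts):
        sub = differential[differential["contrast"] == contrast]
        sig = sub["fdr"] <= fdr_threshold
        with np.errstate(divide="ignore"):
            nlp = -np.log10(sub["p"])
        ax.scatter(sub["log2_fc"][~sig], nlp[~sig], s=8, c="grey", alpha=0.5)
        ax.scatter(sub["log2_fc"][sig], nlp[sig], s=10, c="crimson", alpha=0.7)
        ax.axhline(0, lw=0.5, c="k")
        ax.set_xlabel("log2 FC (ALD vs CTRL)")
        ax.set_ylabel("-log10 p")
        ax.set_title(contrast, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fc_curves(curves: pd.DataFrame, path: PathLike) -> None:
    combos = curves[["comparison", "property"]].drop_duplicates()
    n = len(combos)
    fig, axes = plt.subplots(n, 3, figsize=(10, 2.6 * max(n, 1)), squeeze=False)
    for i, (_, combo) in enumerate(combos.iterrows()):
        for j, nc in enumerate((1, 2, 3)):
            ax = axes[i][j]
            sub = curves[
                (curves["comparison"] == combo["comparison"])
                & (curves["property"] == combo["property"])
                & (curves["n_chains"] == nc)
            ]
            pts = sub[sub["kind"] == "bin"]
            lo = sub[sub["kind"] == "loess"]
            ax.scatter(pts["x"], pts["value"], s=10, c="steelblue")
            ax.plot(lo["x"], lo["value"], c="darkorange")
            ax.axhline(0, lw=0.5, c="k")
            ax.set_title(f"{combo['comparison']} | {nc}-chain", fontsize=8)
            ax.set_xlabel(combo["property"], fontsize=8)
            ax.set_ylabel("log2 FC", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_zscore_heatmap(z: pd.DataFrame, path: PathLike) -> None:
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * z.shape[1]), max(4, 0.25 * z.shape[0])))
    im = ax.imshow(z.values, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_yticks(range(z.shape[0]), z.index, fontsize=7)
    ax.set_xticks(range(z.shape[1]), z.columns, fontsize=6, rotation=90)
    fig.colorbar(im, ax=ax, label="Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(scores: pd.DataFrame, design: pd.DataFrame, path: PathLike) -> None:
    merged = scores.reset_index(names="sample_id").merge(design, on="sample_id", how="left")
    fig, ax = plt.subplots(figsize=(5, 4))
    for tp, sub in merged.groupby("timepoint"):
        for geno, marker in (("CTRL", "o"), ("ALD", "^")):
            g = sub[sub["genotype"] == geno]
            if len(g):
                ax.scatter(g["PC1"], g["PC2"], marker=marker, label=f"d{tp} {geno}", alpha=0.8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
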