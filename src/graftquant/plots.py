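"""Figure helpers (cosmetic; nothing downstream depends on these)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


def plot_group_violin(cohort, ax=None):
    """Violin plot of ddcfDNA fraction per diagnosis group (log scale)."""
    from .cohort import DIAGNOSIS_GROUPS

    ax = ax or plt.gca()
    data = [[r.ddcfdna_fraction for r in cohort if r.diagnosis == g]
            for g in DIAGNOSIS_GROUPS]
    groups = [g for g, d in zip(DIAGNOSIS_GROUPS, data) if d]
    data = [d for d in data if d]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_yscale("log")
    ax.set_ylabel("plasma ddcfDNA (%)")
    return ax


def plot_cluster_heatmap(result, path=None):
    """Heatmap of the standardized density matrix in dendrogram row order."""
    z = result.standardized.iloc[result.row_order]
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(8, 6), gridspec_kw={"width_ratios": [1, 4]})
    hierarchy.dendrogram(result.linkage, orientation="left", ax=ax_d, no_labels=True)
    im = ax_h.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax_h.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=7)
    ax_h.set_yticks([])
    fig.colorbar(im, ax=ax_h, label="z-scored density")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_correlation_matrix(r: pd.DataFrame, path=None):
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(r.index)), r.index, fontsize=7)
    for i in range(len(r.index)):
        for j in range(len(r.columns)):
            v = r.iloc[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
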