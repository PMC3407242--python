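"""Figure writers: sharing heatmap with dendrogram margin, PC scatter,
enrichment bars.  All take precomputed results and write to a path; nothing
here computes statistics."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

from breedline.pca import PcaResult
from breedline.sharing import ClusterOrder, SharingMatrix


def sharing_heatmap(
    s: SharingMatrix,
    order: ClusterOrder,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
) -> Path:
    """Ordered heatmap of A_s with the merge tree in a top margin.

    Color limits default to the data range (excluding the unit diagonal); they
    are configurable because the informative range varies between panels.
    """
    idx = order.order
    vals = s.values[np.ix_(idx, idx)]
    off = vals[~np.eye(len(idx), dtype=bool)]
    vmin = off.min() if vmin is None else vmin
    vmax = off.max() if vmax is None else vmax

    fig = plt.figure(figsize=(8, 9))
    ax_tree = fig.add_axes([0.08, 0.76, 0.84, 0.20])
    dendrogram(order.merges, no_labels=True, ax=ax_tree, color_threshold=0)
    ax_tree.set_axis_off()
    ax_heat = fig.add_axes([0.08, 0.06, 0.84, 0.68])
    im = ax_heat.imshow(vals, cmap="RdBu_r", vmin=vmin, vmax=vmax, aspect="auto")
    ax_heat.set_xticks([])
    ax_heat.set_yticks([])
    fig.colorbar(im, ax=ax_heat, fraction=0.04, label="allele sharing $A_s$")
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def pca_scatter(
    p: PcaResult,
    labels: dict[str, str],
    path: str | Path,
    dims: tuple[int, int] = (0, 1),
) -> Path:
    """Scatter of two principal coordinates, one color per population."""
    i, j = dims
    fig, ax = plt.subplots(figsize=(7, 6))
    pops = sorted({labels[s] for s in p.samples})
    cmap = plt.get_cmap("tab10")
    for k, pop in enumerate(pops):
        mask = np.array([labels[s] == pop for s in p.samples])
        ax.scatter(
            p.coordinates[mask, i],
            p.coordinates[mask, j],
            s=18,
            color=cmap(k % 10),
            label=pop,
        )
    ve = p.variance_explained
    ax.set_xlabel(f"PC{i + 1} ({100 * ve[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * ve[j]:.1f}%)")
    ax.legend(frameon=False)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def enrichment_bars(enrichment, path: str | Path) -> Path:
    """Observed vs expected chromosome share of outlier SNPs."""
    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(enrichment))
    ax.bar(x - 0.2, 100 * enrichment["expected_fraction"], width=0.4, label="expected")
    ax.bar(x + 0.2, 100 * enrichment["observed_fraction"], width=0.4, label="observed")
    ax.set_xticks(x)
    ax.set_xticklabels(enrichment["chromosome"], rotation=90, fontsize=7)
    ax.set_ylabel("% of outlier SNPs")
    ax.set_xlabel("chromosome")
    ax.legend(frameon=False)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
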