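"""QC and result figures.

Every function writes both a raster (.png) and a vector (.pdf) file and
returns the list of paths.  Figures are plain matplotlib; plot bytes
are backend-dependent and excluded from any determinism guarantee.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _save(fig, prefix) -> list[str]:
    paths = [f"{prefix}.png", f"{prefix}.pdf"]
    for p in paths:
        fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths


def plot_filter_distributions(before, after, prefix) -> list[str]:
    """Coverage and rate histograms for the complete vs filtered sets."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for summ, label, alpha in ((before, "all positions", 0.6), (after, "filtered", 0.8)):
        axes[0].bar(
            summ.coverage_bins[:-1], summ.coverage_counts, width=1.0,
            alpha=alpha, label=label,
        )
        centers = (summ.rate_bin_edges[:-1] + summ.rate_bin_edges[1:]) / 2
        axes[1].bar(centers, summ.rate_counts, width=0.01, alpha=alpha, label=label)
    axes[0].set_xlabel("coverage")
    axes[0].set_ylabel("positions")
    axes[1].set_xlabel("methylation rate")
    for ax in axes:
        ax.legend()
    return _save(fig, prefix)


def plot_overview(bundle, prefix) -> list[str]:
    from scipy.cluster.hierarchy import dendrogram

    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    if bundle.linkage_matrix is not None:
        dendrogram(
            bundle.linkage_matrix, labels=bundle.clustered_samples, ax=axes[0, 0]
        )
        axes[0, 0].set_title("sample clustering (complete linkage)")
    centers = np.arange(10) / 10 + 0.05
    width = 0.04
    axes[0, 1].bar(centers - width / 2, bundle.binned_rates_g1, width=width, label="group 1")
    axes[0, 1].bar(centers + width / 2, bundle.binned_rates_g2, width=width, label="group 2")
    axes[0, 1].set_xlabel("mean methylation rate")
    axes[0, 1].legend()
    axes[1, 0].imshow(
        np.log1p(bundle.density_2d.T), origin="lower", extent=[0, 1, 0, 1], aspect="auto"
    )
    axes[1, 0].set_xlabel("group 1 mean")
    axes[1, 0].set_ylabel("group 2 mean")
    diff_centers = (bundle.diff_bin_edges[:-1] + bundle.diff_bin_edges[1:]) / 2
    axes[1, 1].bar(diff_centers, bundle.diff_counts, width=0.045)
    axes[1, 1].set_xlabel("group 1 - group 2 methylation difference")
    return _save(fig, prefix)


def plot_annotation_heatmap(table, clustering, prefix) -> list[str]:
    data = table.loc[clustering.row_order, clustering.col_order]
    fig, ax = plt.subplots(figsize=(6, max(4, 0.2 * len(data))))
    im = ax.imshow(data.to_numpy(), aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90)
    ax.set_yticks(range(len(data.index)), data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="mean methylation rate")
    return _save(fig, prefix)


def plot_dmr_statistics(stats, prefix) -> list[str]:
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    edges, counts = stats.length_nt_hist
    if len(counts):
        axes[0, 0].bar(edges[:-1], counts, width=np.diff(edges), align="edge")
    axes[0, 0].set_xlabel("DMR length (nt)")
    edges, counts = stats.abs_diff_hist
    if len(counts):
        axes[0, 1].bar(edges[:-1], counts, width=np.diff(edges), align="edge")
    axes[0, 1].set_xlabel("|mean methylation difference|")
    if len(stats.group_mean_scatter):
        axes[1, 0].scatter(
            stats.group_mean_scatter[:, 0], stats.group_mean_scatter[:, 1], s=12
        )
    axes[1, 0].set_xlabel("group 1 mean")
    axes[1, 0].set_ylabel("group 2 mean")
    axes[1, 0].set_xlim(0, 1)
    axes[1, 0].set_ylim(0, 1)
    if len(stats.diff_vs_q_scatter):
        axes[1, 1].scatter(
            stats.diff_vs_q_scatter[:, 0],
            -np.log10(np.maximum(stats.diff_vs_q_scatter[:, 1], 1e-300)),
            s=12,
        )
    axes[1, 1].set_xlabel("mean methylation difference")
    axes[1, 1].set_ylabel("-log10 q")
    return _save(fig, prefix)


def plot_correlation_pair(record, prefix) -> list[str]:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    pts = record.points
    ax.scatter(pts["methylation"], pts["expression"])
    r = "NA" if record.pearson_r is None else f"{record.pearson_r:.2f}"
    rho = "NA" if record.spearman_rho is None else f"{record.spearman_rho:.2f}"
    ax.set_title(f"{record.dmr_id} vs {record.gene_id} (r={r}, rho={rho})")
    ax.set_xlabel("DMR methylation")
    ax.set_ylabel("expression")
    return _save(fig, prefix)
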