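"""Aggregate methylation over annotation regions (TFBS, CpG islands,
promoters, ...) and cluster the resulting region x sample table.

A region's cell for a sample is the mean of that sample's defined rates
at positions falling inside the region (BED 0-based half-open overlap);
cells backed by fewer than ``min_positions`` positions are withheld as
too noisy.  Overlapping regions are scored independently, so one
position may contribute to several regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import AnnotationItem, SampleMatrix


@dataclass
class RegionAggregate:
    table: pd.DataFrame  # region x sample mean rates (NaN = withheld)
    group_means: pd.DataFrame | None  # region x {group1, group2}
    n_positions: pd.Series  # positions overlapping each region
    dropped_regions: list  # all cells missing


def aggregate_over_regions(
    matrix: SampleMatrix,
    regions: list[AnnotationItem],
    min_positions: int = 3,
    group1: list[str] | None = None,
    group2: list[str] | None = None,
) -> RegionAggregate:
    if not regions:
        raise ValueError("region file is empty")
    if matrix.n_positions == 0:
        raise ValueError("sample matrix is empty")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = np.array([p[0] for p in matrix.positions])
    pos0 = np.array([p[1] - 1 for p in matrix.positions])  # 0-based
    order_rows = np.arange(matrix.n_positions)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        by_chrom[chrom] = (pos0[mask], order_rows[mask])

    rows = []
    counts = []
    for region in regions:
        if region.chrom not in by_chrom:
            rows.append(np.full(matrix.n_samples, np.nan))
            counts.append(0)
            continue
        cpos, cidx = by_chrom[region.chrom]
        lo = np.searchsorted(cpos, region.start, side="left")
        hi = np.searchsorted(cpos, region.end, side="left")
        idx = cidx[lo:hi]
        counts.append(len(idx))
        if len(idx) == 0:
            rows.append(np.full(matrix.n_samples, np.nan))
            continue
        sub = matrix.values[idx]
        n_def = (~np.isnan(sub)).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(sub, axis=0)
        means[n_def < min_positions] = np.nan
        rows.append(means)

    table = pd.DataFrame(
        np.vstack(rows), index=[r.name for r in regions], columns=matrix.sample_names
    )
    n_positions = pd.Series(counts, index=table.index, name="n_positions")
    dropped = table.index[table.isna().all(axis=1)].tolist()
    table = table.drop(index=dropped)

    group_means = None
    if group1 and group2:
        group_means = pd.DataFrame(
            {
                "group1": table[group1].mean(axis=1),
                "group2": table[group2].mean(axis=1),
            }
        )
    return RegionAggregate(table, group_means, n_positions, dropped)


@dataclass
class HeatmapClustering:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_region_heatmap(table: pd.DataFrame) -> HeatmapClustering:
    """Hierarchically cluster regions (rows) and samples (columns) with
    complete linkage on Euclidean distance; rows with any missing cell
    are compared over pairwise-complete columns."""
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            "need >= 2 regions and >= 2 samples after dropping empty regions; "
            "consider lowering min_positions"
        )

    def _linkage_for(data: np.ndarray) -> np.ndarray:
        if np.isnan(data).any():
            n = data.shape[0]
            dist = np.zeros(n * (n - 1) // 2)
            k = 0
            for a in range(n):
                for b in range(a + 1, n):
                    shared = ~np.isnan(data[a]) & ~np.isnan(data[b])
                    if shared.sum() == 0:
                        raise ValueError(
                            "rows with no shared defined cells; lower min_positions"
                        )
                    d = data[a, shared] - data[b, shared]
                    dist[k] = np.sqrt((d * d).sum())
                    k += 1
        else:
            dist = pdist(data, metric="euclidean")
        return linkage(dist, method="complete")

    row_link = _linkage_for(table.to_numpy())
    col_link = _linkage_for(table.to_numpy().T)
    row_order = [table.index[i] for i in leaves_list(row_link)]
    col_order = [table.columns[i] for i in leaves_list(col_link)]
    return HeatmapClustering(row_order, col_order, row_link, col_link)


def per_region_boxplot_tables(agg: RegionAggregate) -> dict[str, pd.DataFrame]:
    """Two complementary views of region methylation: per-region means
    pooled over samples, and per-sample means pooled over regions."""
    per_region = agg.table.mean(axis=1, skipna=True).to_frame("mean_rate")
    per_sample = agg.table.mean(axis=0, skipna=True).to_frame("mean_rate")
    return {"per_region": per_region, "per_sample": per_sample}
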