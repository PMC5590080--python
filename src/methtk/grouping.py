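"""Combine per-sample methylation calls into two labelled groups.

The sample matrix is the union of positions over all samples; an entry
is missing (NaN) when that sample's coverage at the position is below
the build threshold.  Group summaries then retain only positions where
each group has at least ``min_samples`` covered samples, and report the
unweighted mean rate per group and the between-group difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .io import GroupSummary, MethylationRecord, SampleMatrix


def build_sample_matrix(
    sample_records: list[list[MethylationRecord]],
    sample_names: list[str],
    min_coverage_per_sample: int = 10,
) -> SampleMatrix:
    """Assemble the positions x samples rate matrix from per-sample calls."""
    if len(sample_records) != len(sample_names):
        raise ValueError("one record list per sample name required")
    if len(set(sample_names)) != len(sample_names):
        raise ValueError("duplicate sample names")
    if not sample_records:
        raise ValueError("at least one sample required")

    position_set: set[tuple] = set()
    for records in sample_records:
        for r in records:
            position_set.add((r.chrom, r.pos, r.strand, r.context))
    positions = sorted(position_set, key=lambda p: (p[0], p[1], p[2]))
    index = {p: i for i, p in enumerate(positions)}

    n, s = len(positions), len(sample_names)
    values = np.full((n, s), np.nan)
    coverages = np.zeros((n, s), dtype=int)
    for j, records in enumerate(sample_records):
        for r in records:
            i = index[(r.chrom, r.pos, r.strand, r.context)]
            coverages[i, j] = r.coverage
            if r.coverage >= min_coverage_per_sample and r.coverage > 0:
                values[i, j] = r.rate
    if n == 0:
        warnings.warn("no positions shared with any sample; matrix is empty")
    return SampleMatrix(positions, sample_names, values, coverages)


def summarize_groups(
    matrix: SampleMatrix,
    group1: list[str],
    group2: list[str],
    min_samples: int = 1,
) -> GroupSummary:
    """Per-position group means and difference, gated on per-group support.

    A position is retained iff each group has >= ``min_samples`` samples
    with a defined (sufficiently covered) rate there.  Means are
    unweighted over the available samples.
    """
    if not group1 or not group2:
        raise ValueError("both groups must be nonempty")
    if set(group1) & set(group2):
        raise ValueError(f"groups overlap: {sorted(set(group1) & set(group2))}")
    if min_samples > min(len(group1), len(group2)):
        raise ValueError("min_samples exceeds a group's size")
    idx1 = [matrix.sample_index(name) for name in group1]
    idx2 = [matrix.sample_index(name) for name in group2]

    v1 = matrix.values[:, idx1]
    v2 = matrix.values[:, idx2]
    n1 = (~np.isnan(v1)).sum(axis=1)
    n2 = (~np.isnan(v2)).sum(axis=1)
    keep = (n1 >= min_samples) & (n2 >= min_samples)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # mean of empty slice
        mean1 = np.nanmean(v1, axis=1)
        mean2 = np.nanmean(v2, axis=1)

    positions = [p for p, k in zip(matrix.positions, keep) if k]
    return GroupSummary(
        positions=positions,
        mean_g1=mean1[keep],
        mean_g2=mean2[keep],
        n_covered_g1=n1[keep],
        n_covered_g2=n2[keep],
        group1=list(group1),
        group2=list(group2),
    )


# ---------------------------------------------------------------------------
# overview statistics


@dataclass
class OverviewBundle:
    distance_matrix: np.ndarray  # samples x samples, NaN where undefined
    linkage_matrix: np.ndarray | None  # scipy linkage over usable samples
    clustered_samples: list[str]
    excluded_samples: list[str]
    binned_rates_g1: np.ndarray  # counts per 0.1-wide bin, 10 bins
    binned_rates_g2: np.ndarray
    boxplot_g1: dict  # five-number summary of per-position group means
    boxplot_g2: dict
    density_2d: np.ndarray  # 2-D histogram of (mean_g1, mean_g2)
    density_edges: np.ndarray
    diff_bin_edges: np.ndarray  # width 0.05 over [-1, 1]
    diff_counts: np.ndarray


def _five_number(x: np.ndarray) -> dict:
    if len(x) == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
    }


def pairwise_sample_distances(matrix: SampleMatrix) -> np.ndarray:
    """Euclidean distance between sample methylation profiles, computed
    over the positions both samples share; NaN when <2 shared positions."""
    s = matrix.n_samples
    dist = np.zeros((s, s))
    for a in range(s):
        for b in range(a + 1, s):
            shared = ~np.isnan(matrix.values[:, a]) & ~np.isnan(matrix.values[:, b])
            if shared.sum() < 2:
                dist[a, b] = dist[b, a] = np.nan
                continue
            d = matrix.values[shared, a] - matrix.values[shared, b]
            dist[a, b] = dist[b, a] = float(np.sqrt((d * d).sum()))
    return dist


def overview_statistics(
    matrix: SampleMatrix, summary: GroupSummary
) -> OverviewBundle:
    """Dataset-level QC: sample clustering, binned group-mean distributions,
    boxplot summaries, a 2-D density of the group means and the histogram
    of between-group differences."""
    if matrix.n_samples < 2:
        raise ValueError("clustering requires at least 2 samples")
    dist = pairwise_sample_distances(matrix)

    usable = [
        i
        for i in range(matrix.n_samples)
        if not np.isnan(np.delete(dist[i], i)).all()
    ]
    excluded = [matrix.sample_names[i] for i in range(matrix.n_samples) if i not in usable]
    if excluded:
        warnings.warn(f"samples excluded from clustering (no shared positions): {excluded}")
    sub = dist[np.ix_(usable, usable)]
    link = None
    if len(usable) >= 2 and not np.isnan(sub).any():
        condensed = sub[np.triu_indices(len(usable), k=1)]
        link = linkage(condensed, method="complete")

    edges10 = np.linspace(0.0, 1.0, 11)
    binned1 = np.histogram(summary.mean_g1, bins=edges10)[0]
    binned2 = np.histogram(summary.mean_g2, bins=edges10)[0]

    density_edges = np.linspace(0.0, 1.0, 51)
    density = np.histogram2d(summary.mean_g1, summary.mean_g2, bins=[density_edges] * 2)[0]

    diff_edges = np.arange(-1.0, 1.0 + 0.05 / 2, 0.05)
    diff_counts = np.histogram(summary.diff, bins=diff_edges)[0]

    return OverviewBundle(
        distance_matrix=dist,
        linkage_matrix=link,
        clustered_samples=[matrix.sample_names[i] for i in usable],
        excluded_samples=excluded,
        binned_rates_g1=binned1,
        binned_rates_g2=binned2,
        boxplot_g1=_five_number(summary.mean_g1),
        boxplot_g2=_five_number(summary.mean_g2),
        density_2d=density,
        density_edges=density_edges,
        diff_bin_edges=diff_edges,
        diff_counts=diff_counts,
    )


def genomewide_binned_means(matrix: SampleMatrix, bin_size: int = 1_000_000) -> pd.DataFrame:
    """Mean rate per sample in fixed genomic bins (a plain-text stand-in
    for a genome-wide heatmap).  Only bins with >= 1 covered position per
    any sample are emitted; cells with no covered position are NaN."""
    if matrix.n_positions == 0:
        return pd.DataFrame(columns=["chrom", "bin_start", "bin_end", *matrix.sample_names])
    chroms = np.array([p[0] for p in matrix.positions])
    pos0 = np.array([p[1] - 1 for p in matrix.positions])
    bins = pos0 // bin_size
    df = pd.DataFrame(matrix.values, columns=matrix.sample_names)
    df["chrom"] = chroms
    df["bin"] = bins
    grouped = df.groupby(["chrom", "bin"], sort=True)[matrix.sample_names].mean()
    grouped = grouped.reset_index()
    grouped.insert(1, "bin_start", grouped.pop("bin") * bin_size)
    grouped.insert(2, "bin_end", grouped["bin_start"] + bin_size)
    return grouped
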