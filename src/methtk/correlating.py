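"""Correlate DMR methylation with gene expression across samples.

For each user-supplied (DMR, gene) pair, the per-sample DMR methylation
(mean of that sample's rates over the DMR's positions) is correlated
with the gene's expression over the samples present in both data sets:
Pearson r captures linear association, Spearman rho any monotone
association.  Pairs whose largest absolute coefficient reaches the
cutoff are nominated as correlating DMRs (cDMRs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .io import DMR, SampleMatrix

MIN_POSITIONS_PER_SAMPLE = 2
MIN_USABLE_SAMPLES = 3


@dataclass
class PairRecord:
    dmr_id: str
    gene_id: str
    pearson_r: float | None
    spearman_rho: float | None
    n_samples: int
    points: pd.DataFrame  # per-sample (methylation, expression)
    flag: str = "ok"  # ok | too_few_samples | zero_variance


def dmr_sample_methylation(matrix: SampleMatrix, dmr: DMR) -> pd.Series:
    """Per-sample mean rate over the DMR's positions; a sample is missing
    when it has fewer than 2 covered positions inside the region."""
    idx = [
        i
        for i, p in enumerate(matrix.positions)
        if p[0] == dmr.chrom and dmr.start <= p[1] - 1 < dmr.end
    ]
    if not idx:
        return pd.Series(np.nan, index=matrix.sample_names)
    sub = matrix.values[idx]
    n_def = (~np.isnan(sub)).sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(sub, axis=0)
    means[n_def < MIN_POSITIONS_PER_SAMPLE] = np.nan
    return pd.Series(means, index=matrix.sample_names)


def correlate_pairs(
    dmrs: list[DMR],
    matrix: SampleMatrix,
    expression: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> list[PairRecord]:
    """Pearson and Spearman coefficients for every DMR-gene pair."""
    dmr_by_id = {d.name: d for d in dmrs}
    unknown_dmrs = sorted({d for d, _g in pairs} - dmr_by_id.keys())
    unknown_genes = sorted({g for _d, g in pairs} - set(expression.index))
    if unknown_dmrs or unknown_genes:
        raise KeyError(
            f"unknown ids in pair table: DMRs {unknown_dmrs}, genes {unknown_genes}"
        )
    shared = [s for s in matrix.sample_names if s in expression.columns]
    if len(shared) < MIN_USABLE_SAMPLES:
        raise ValueError(
            f"need >= {MIN_USABLE_SAMPLES} samples shared between methylation "
            f"and expression, found {len(shared)}"
        )

    meth_cache: dict[str, pd.Series] = {}
    out: list[PairRecord] = []
    for dmr_id, gene_id in pairs:
        if dmr_id not in meth_cache:
            meth_cache[dmr_id] = dmr_sample_methylation(matrix, dmr_by_id[dmr_id])
        meth = meth_cache[dmr_id][shared]
        expr = expression.loc[gene_id, shared].astype(float)
        usable = meth.notna() & expr.notna()
        points = pd.DataFrame(
            {"methylation": meth[usable], "expression": expr[usable]}
        )
        n = int(usable.sum())
        if n < MIN_USABLE_SAMPLES:
            out.append(PairRecord(dmr_id, gene_id, None, None, n, points, "too_few_samples"))
            continue
        m = points["methylation"].to_numpy()
        e = points["expression"].to_numpy()
        if np.ptp(m) == 0 or np.ptp(e) == 0:
            out.append(PairRecord(dmr_id, gene_id, None, None, n, points, "zero_variance"))
            continue
        r = float(pearsonr(m, e).statistic)
        rho = float(spearmanr(m, e).statistic)
        out.append(PairRecord(dmr_id, gene_id, r, rho, n, points))
    return out


def correlation_report(
    records: list[PairRecord], cutoff: float = 0.8
) -> pd.DataFrame:
    """cDMR table: pairs with max(|r|, |rho|) >= cutoff, sorted by
    descending absolute coefficient.  Anticorrelation counts."""
    rows = []
    for rec in records:
        if rec.flag != "ok":
            continue
        best = max(abs(rec.pearson_r), abs(rec.spearman_rho))
        if best >= cutoff:
            rows.append(
                {
                    "dmr_id": rec.dmr_id,
                    "gene_id": rec.gene_id,
                    "pearson_r": rec.pearson_r,
                    "spearman_rho": rec.spearman_rho,
                    "best_abs_coefficient": best,
                    "n_samples": rec.n_samples,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "dmr_id", "gene_id", "pearson_r", "spearman_rho",
            "best_abs_coefficient", "n_samples",
        ],
    )
    return df.sort_values("best_abs_coefficient", ascending=False).reset_index(drop=True)
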