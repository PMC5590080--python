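"""Coverage- and context-based filtering of called cytosines.

Lowly covered positions carry noisy rate estimates; very highly covered
positions are typically mapping artifacts (collapsed repeats), so the
default upper cutoff adapts to the library: positions above the 99.9th
percentile of the sample's own coverage distribution are removed unless
an absolute cap is given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import CONTEXTS, MethylationRecord

N_RATE_BINS = 100


@dataclass
class FilterSpec:
    min_coverage: int = 10
    max_coverage: int | None = None  # absolute cap; wins over the quantile rule
    max_coverage_quantile: float | None = 0.999
    contexts: frozenset = frozenset({"CG"})

    def __post_init__(self):
        self.contexts = frozenset(self.contexts)
        unknown = self.contexts - set(CONTEXTS)
        if unknown:
            raise ValueError(f"unknown contexts: {sorted(unknown)}")
        if self.max_coverage is not None and self.min_coverage > self.max_coverage:
            raise ValueError("min_coverage exceeds max_coverage")
        if self.max_coverage_quantile is not None and not (
            0 < self.max_coverage_quantile <= 1
        ):
            raise ValueError("max_coverage_quantile must be in (0, 1]")

    def resolve_max(self, coverages: np.ndarray) -> float:
        if self.max_coverage is not None:
            return float(self.max_coverage)
        if self.max_coverage_quantile is None or len(coverages) == 0:
            return math.inf
        return float(np.quantile(coverages, self.max_coverage_quantile))


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    per_context_input: dict
    per_context_kept: dict
    resolved_max_coverage: float

    def to_lines(self):
        yield f"positions_input\t{self.n_input}"
        yield f"positions_kept\t{self.n_kept}"
        yield f"resolved_max_coverage\t{self.resolved_max_coverage:g}"
        for ctx in CONTEXTS:
            yield f"input_{ctx}\t{self.per_context_input.get(ctx, 0)}"
            yield f"kept_{ctx}\t{self.per_context_kept.get(ctx, 0)}"


def filter_records(
    records: list[MethylationRecord], spec: FilterSpec
) -> tuple[list[MethylationRecord], FilterReport]:
    """Keep records with min_coverage <= coverage <= resolved max and an
    allowed context.  Both coverage bounds are inclusive."""
    coverages = np.array([r.coverage for r in records], dtype=float)
    max_cov = spec.resolve_max(coverages)
    kept = [
        r
        for r in records
        if spec.min_coverage <= r.coverage <= max_cov and r.context in spec.contexts
    ]
    per_in: dict[str, int] = {}
    per_out: dict[str, int] = {}
    for r in records:
        per_in[r.context] = per_in.get(r.context, 0) + 1
    for r in kept:
        per_out[r.context] = per_out.get(r.context, 0) + 1
    report = FilterReport(len(records), len(kept), per_in, per_out, max_cov)
    return kept, report


def destrand(records: list[MethylationRecord]) -> list[MethylationRecord]:
    """Merge the symmetric strands of CpG dinucleotides.

    A + strand CG record at pos and a - strand CG record at pos+1 describe
    the same CpG; their counts are summed onto the + record.  Non-CG
    records and unpaired CG records pass through unchanged.
    """
    by_key = {(r.chrom, r.pos, r.strand): r for r in records}
    out: list[MethylationRecord] = []
    consumed: set[tuple] = set()
    for r in sorted(records, key=MethylationRecord.sort_key):
        key = (r.chrom, r.pos, r.strand)
        if key in consumed:
            continue
        if r.context != "CG":
            out.append(r)
            continue
        if r.strand == "+":
            mate = by_key.get((r.chrom, r.pos + 1, "-"))
            if mate is not None and mate.context == "CG":
                consumed.add((mate.chrom, mate.pos, mate.strand))
                r = MethylationRecord(
                    r.chrom, r.pos, "+", "CG",
                    r.n_meth + mate.n_meth, r.n_unmeth + mate.n_unmeth,
                )
            out.append(r)
        else:
            # a - record whose + mate exists is consumed when the mate is seen
            if (r.chrom, r.pos - 1, "+") in by_key and by_key[
                (r.chrom, r.pos - 1, "+")
            ].context == "CG":
                continue
            out.append(r)
    out.sort(key=MethylationRecord.sort_key)
    return out


@dataclass
class DistributionSummary:
    coverage_bins: np.ndarray  # bin edges, integers 0..max+1
    coverage_counts: np.ndarray
    rate_bin_edges: np.ndarray  # 101 edges over [0, 1]
    rate_counts: np.ndarray
    n_records: int = 0
    n_with_rate: int = 0


def _summarize(records: list[MethylationRecord]) -> DistributionSummary:
    coverages = np.array([r.coverage for r in records], dtype=int)
    rates = np.array([r.rate for r in records if r.coverage > 0], dtype=float)
    max_cov = int(coverages.max()) if len(coverages) else 0
    cov_bins = np.arange(max_cov + 2)
    cov_counts = np.bincount(coverages, minlength=max_cov + 1) if len(coverages) else np.zeros(1, int)
    edges = np.linspace(0.0, 1.0, N_RATE_BINS + 1)
    # left-closed right-open bins except the last, which is closed at 1.0
    rate_counts = np.histogram(rates, bins=edges)[0] if len(rates) else np.zeros(N_RATE_BINS, int)
    return DistributionSummary(
        coverage_bins=cov_bins,
        coverage_counts=cov_counts,
        rate_bin_edges=edges,
        rate_counts=rate_counts,
        n_records=len(records),
        n_with_rate=len(rates),
    )


def distribution_summaries(
    records_before: list[MethylationRecord], records_after: list[MethylationRecord]
) -> tuple[DistributionSummary, DistributionSummary]:
    """Coverage and methylation-rate histograms for the complete and the
    filtered position sets (the data behind the filtering QC plots)."""
    return _summarize(records_before), _summarize(records_after)
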