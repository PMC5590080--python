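"""Differentially methylated region (DMR) detection.

The group methylation difference signal (per-position difference of the
two group means) is segmented by recursive binary segmentation in the
style of circular binary segmentation on a linear signal: within a
window, the contiguous sub-interval (>= ``min_cpg`` positions) whose
mean difference deviates most in absolute value from the window mean is
selected, and the recursion descends into the selected segment and its
flanks as long as a two-sample two-dimensional Kolmogorov-Smirnov test
between the groups' per-position rates keeps improving.  Terminal
candidates are scored with a two-sided Mann-Whitney U test on the
per-position group means; Benjamini-Hochberg correction over all
candidates genome-wide yields q-values, and reported DMRs must pass the
q, effect-size, size and (optionally) length filters.

Positions further apart than ``max_gap`` are never joined into one
window; methylation is spatially correlated only over short distances,
so distant positions carry no evidence about one another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DMR, GroupSummary
from .stats import benjamini_hochberg, ks2d_pvalue, mann_whitney


@dataclass
class SegmentationParams:
    max_gap: int = 300  # bp between adjacent positions within one window
    min_cpg: int = 10  # minimum tested positions per candidate
    min_diff: float = 0.1  # minimum |mean methylation difference|
    max_q: float = 0.05  # BH-corrected significance cutoff
    min_length_nt: int | None = None

    def __post_init__(self):
        if self.max_gap <= 0 or self.min_diff < 0 or self.max_q <= 0:
            raise ValueError("parameters must be positive")
        if self.min_cpg < 2:
            raise ValueError("min_cpg must be >= 2")


@dataclass
class Candidate:
    chrom: str
    index_lo: int  # inclusive, into the summary's position list
    index_hi: int  # inclusive
    mean_g1: float
    mean_g2: float
    p_mwu: float
    p_ks2d: float

    @property
    def n_cpg(self) -> int:
        return self.index_hi - self.index_lo + 1

    @property
    def mean_diff(self) -> float:
        return self.mean_g1 - self.mean_g2


def presegment(summary: GroupSummary, max_gap: int) -> list[tuple[int, int]]:
    """Partition retained positions into runs: consecutive positions of a
    run share a chromosome and are <= max_gap bp apart.  Returned as
    (start, end) index pairs, end exclusive."""
    n = len(summary)
    if n == 0:
        return []
    chroms = [p[0] for p in summary.positions]
    pos = np.array([p[1] for p in summary.positions])
    runs = []
    start = 0
    for i in range(1, n):
        if chroms[i] != chroms[i - 1] or pos[i] - pos[i - 1] > max_gap:
            runs.append((start, i))
            start = i
    runs.append((start, n))
    return runs


def maximal_mean_segment(
    diff: np.ndarray, min_len: int
) -> tuple[int, int] | None:
    """The contiguous sub-interval of length >= min_len maximizing the
    absolute mean of ``diff``.  Ties broken leftmost, then shortest.
    Returns (lo, hi) inclusive, or None when the window is too short."""
    n = len(diff)
    if n < min_len:
        return None
    cs = np.concatenate([[0.0], np.cumsum(diff)])
    best_score = -np.inf
    best = None
    for length in range(min_len, n + 1):
        means = np.abs(cs[length:] - cs[: n - length + 1]) / length
        start = int(np.argmax(means))
        score = float(means[start])
        # strict improvement keeps the leftmost-then-shortest winner
        if score > best_score or (
            score == best_score and best is not None and start < best[0]
        ):
            best_score = score
            best = (start, start + length - 1)
    return best


def _ks2d_points(mean_g1: np.ndarray, mean_g2: np.ndarray, lo: int, hi: int):
    ranks = np.arange(hi - lo + 1, dtype=float)
    a = np.column_stack([ranks, mean_g1[lo : hi + 1]])
    b = np.column_stack([ranks, mean_g2[lo : hi + 1]])
    return a, b


def segment_run(
    mean_g1: np.ndarray,
    mean_g2: np.ndarray,
    params: SegmentationParams,
) -> list[tuple[int, int]]:
    """Segment one window of the difference signal into candidate
    intervals ((lo, hi) inclusive indices into the window)."""
    diff = mean_g1 - mean_g2
    if np.isnan(diff).all():
        warnings.warn("window with all-missing differences skipped")
        return []
    out: list[tuple[int, int]] = []

    def ks_p(lo: int, hi: int) -> float:
        a, b = _ks2d_points(mean_g1, mean_g2, lo, hi)
        return ks2d_pvalue(a, b)[1]

    def recurse(lo: int, hi: int) -> None:
        if hi - lo + 1 < params.min_cpg:
            return
        seg = maximal_mean_segment(diff[lo : hi + 1], params.min_cpg)
        if seg is None:
            return
        seg = (seg[0] + lo, seg[1] + lo)
        if seg == (lo, hi):
            out.append((lo, hi))
            return
        p_region = ks_p(lo, hi)
        p_seg = ks_p(*seg)
        if p_seg < p_region:
            recurse(*seg)
            recurse(lo, seg[0] - 1)
            recurse(seg[1] + 1, hi)
        else:
            out.append((lo, hi))

    recurse(0, len(diff) - 1)
    out.sort()
    return out


def test_region(mean_g1: np.ndarray, mean_g2: np.ndarray) -> tuple[float, float]:
    """Score one candidate: two-sided Mann-Whitney U on the per-position
    group-mean vectors, and the 2-D KS test on {(position rank, rate)}.

    Degenerate candidates (zero variance in both groups, zero difference)
    return p = 1 for both tests.
    """
    mean_g1 = np.asarray(mean_g1, dtype=float)
    mean_g2 = np.asarray(mean_g2, dtype=float)
    if (
        np.ptp(mean_g1) == 0
        and np.ptp(mean_g2) == 0
        and mean_g1[0] == mean_g2[0]
    ):
        return 1.0, 1.0
    p_mwu = mann_whitney(mean_g1, mean_g2)
    a, b = _ks2d_points(mean_g1, mean_g2, 0, len(mean_g1) - 1)
    _, p_ks = ks2d_pvalue(a, b)
    return p_mwu, p_ks


def find_candidates(
    summary: GroupSummary, params: SegmentationParams
) -> list[Candidate]:
    """Segment every window and test every terminal candidate."""
    candidates: list[Candidate] = []
    for run_lo, run_hi in presegment(summary, params.max_gap):
        if run_hi - run_lo < params.min_cpg:
            continue
        m1 = summary.mean_g1[run_lo:run_hi]
        m2 = summary.mean_g2[run_lo:run_hi]
        for lo, hi in segment_run(m1, m2, params):
            g1 = m1[lo : hi + 1]
            g2 = m2[lo : hi + 1]
            p_mwu, p_ks = test_region(g1, g2)
            candidates.append(
                Candidate(
                    chrom=summary.positions[run_lo + lo][0],
                    index_lo=run_lo + lo,
                    index_hi=run_lo + hi,
                    mean_g1=float(g1.mean()),
                    mean_g2=float(g2.mean()),
                    p_mwu=p_mwu,
                    p_ks2d=p_ks,
                )
            )
    return candidates


def call_dmrs(
    summary: GroupSummary,
    params: SegmentationParams | None = None,
) -> list[DMR]:
    """Full DMR call: segment, test, BH-correct (over p_mwu, genome-wide),
    filter, and name the reported regions DMR_1.. in genomic sort order."""
    params = params or SegmentationParams()
    candidates = find_candidates(summary, params)
    if not candidates:
        return []
    qvals = benjamini_hochberg([c.p_mwu for c in candidates])

    kept: list[tuple[Candidate, float]] = []
    for cand, q in zip(candidates, qvals):
        if q > params.max_q or abs(cand.mean_diff) < params.min_diff:
            continue
        start = summary.positions[cand.index_lo][1] - 1  # 0-based inclusive
        end = summary.positions[cand.index_hi][1]  # 0-based exclusive
        if params.min_length_nt is not None and end - start < params.min_length_nt:
            continue
        kept.append((cand, float(q)))

    kept.sort(key=lambda cq: (cq[0].chrom, summary.positions[cq[0].index_lo][1]))
    dmrs = []
    for k, (cand, q) in enumerate(kept, start=1):
        start = summary.positions[cand.index_lo][1] - 1
        end = summary.positions[cand.index_hi][1]
        dmrs.append(
            DMR(
                chrom=cand.chrom,
                start=start,
                end=end,
                n_cpg=cand.n_cpg,
                mean_g1=cand.mean_g1,
                mean_g2=cand.mean_g2,
                p_mwu=cand.p_mwu,
                p_ks2d=cand.p_ks2d,
                q=q,
                name=f"DMR_{k}",
            )
        )
    return dmrs


def dmr_positions(summary: GroupSummary, dmr: DMR) -> list[int]:
    """Indices of the summary positions inside a DMR's interval."""
    return [
        i
        for i, p in enumerate(summary.positions)
        if p[0] == dmr.chrom and dmr.start <= p[1] - 1 < dmr.end
    ]


# ---------------------------------------------------------------------------
# summary statistics of a filtered DMR set


@dataclass
class DMRStatistics:
    length_nt_hist: tuple  # (edges, counts)
    n_cpg_hist: tuple
    abs_diff_hist: tuple
    group_mean_scatter: np.ndarray  # columns mean_g1, mean_g2
    diff_vs_q_scatter: np.ndarray  # columns mean_diff, q


def dmr_statistics(dmrs: list[DMR]) -> DMRStatistics:
    lengths = np.array([d.length_nt for d in dmrs], dtype=float)
    n_cpgs = np.array([d.n_cpg for d in dmrs], dtype=float)
    diffs = np.array([abs(d.mean_diff) for d in dmrs], dtype=float)
    if len(dmrs):
        len_hist = np.histogram(lengths, bins=min(20, max(len(dmrs), 1)))
        cpg_hist = np.histogram(n_cpgs, bins=min(20, max(len(dmrs), 1)))
        diff_hist = np.histogram(diffs, bins=np.linspace(0, 1, 21))
    else:
        len_hist = (np.array([]), np.array([]))
        cpg_hist = (np.array([]), np.array([]))
        diff_hist = (np.array([]), np.array([]))
    scatter1 = np.array([[d.mean_g1, d.mean_g2] for d in dmrs]).reshape(-1, 2)
    scatter2 = np.array([[d.mean_diff, d.q] for d in dmrs]).reshape(-1, 2)
    return DMRStatistics(
        length_nt_hist=(len_hist[1], len_hist[0]) if len(dmrs) else len_hist,
        n_cpg_hist=(cpg_hist[1], cpg_hist[0]) if len(dmrs) else cpg_hist,
        abs_diff_hist=(diff_hist[1], diff_hist[0]) if len(dmrs) else diff_hist,
        group_mean_scatter=scatter1,
        diff_vs_q_scatter=scatter2,
    )
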