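"""Synthetic bisulfite data with known truth for every pipeline stage.

The generator emulates a small two-group whole-genome bisulfite study
(default: two groups of four samples, the shape of a typical
case-control comparison): a random reference with a controlled CpG
density, per-cytosine methylation counts under a beta-binomial model,
optional paired-end reads for the calling stage, and gene expression
linked to planted DMRs.

Count model
-----------
Per position and sample, coverage ~ Poisson(mean_coverage) and
n_meth | coverage ~ beta-binomial(coverage, rate, dispersion), where
``dispersion`` (rho in [0, 1)) is the intra-class correlation of the
beta mixing distribution: the sampled per-molecule methylation
probability is Beta(rate * s, (1 - rate) * s) with s = (1 - rho) / rho.
rho -> 0 recovers the pure binomial.  The variance of the empirical
rate given coverage c is rate * (1 - rate) * (1 + (c - 1) * rho) / c,
which the moment tests check in closed form.

Baseline rates follow the bimodal profile of mammalian CpG methylation
(mostly high, a low-methylated minority, some intermediate).  Inside a
planted DMR the group rates are baseline +/- delta/2; DMR baselines are
drawn so the shift never clips at 0 or 1, keeping the planted effect
size exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .calling import classify_context
from .io import MethylationRecord, write_expression_table, write_methylation_vcf, write_pairs_table


@dataclass
class CytosineMap:
    """All reference cytosines of one genome with strand and context."""

    chrom_order: list
    chroms: np.ndarray  # per cytosine
    positions: np.ndarray  # 1-based
    strands: np.ndarray
    contexts: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, mask: np.ndarray) -> "CytosineMap":
        return CytosineMap(
            self.chrom_order,
            self.chroms[mask],
            self.positions[mask],
            self.strands[mask],
            self.contexts[mask],
        )


@dataclass
class PlantedDMR:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    delta: float  # true group1 - group2 difference
    index_lo: int  # into the CG-position subset used for planting
    index_hi: int  # inclusive


@dataclass
class SimulationTruth:
    planted_dmrs: list
    baseline_rates: np.ndarray  # aligned with the cytosine map
    rates_g1: np.ndarray
    rates_g2: np.ndarray
    dispersion: float
    expression_links: list = field(default_factory=list)  # (dmr_name, gene, sign)

    def dmr_name(self, i: int) -> str:
        return f"true_dmr_{i + 1}"

    def to_json(self, path, cyt_map: CytosineMap | None = None) -> None:
        payload = {
            "dispersion": self.dispersion,
            "planted_dmrs": [
                {
                    "name": self.dmr_name(i),
                    "chrom": d.chrom,
                    "start": int(d.start),
                    "end": int(d.end),
                    "delta": float(d.delta),
                }
                for i, d in enumerate(self.planted_dmrs)
            ],
            "expression_links": [
                {"dmr": d, "gene": g, "sign": int(s)}
                for d, g, s in self.expression_links
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# reference


def simulate_reference(
    n_chrom: int = 1,
    length: int = 255_000,
    cpg_density: float = 0.02,
    seed: int = 0,
) -> tuple[dict, CytosineMap]:
    """Random reference with CpG dinucleotides planted at ``cpg_density``
    per emission step; accidental CpGs are suppressed so the density
    knob fully controls the CpG content (density 0 -> no CpGs at all).

    Returns ({chrom: sequence}, cytosine map).  Deterministic per seed.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        seqs[chrom] = _simulate_chrom(length, cpg_density, rng)
    return seqs, build_cytosine_map(seqs)


def _simulate_chrom(length: int, cpg_density: float, rng) -> str:
    # each step emits "CG" with prob cpg_density, else one random base;
    # accidental C,G adjacencies are broken afterwards (G -> A)
    n_steps = length  # upper bound; trimmed below
    plant = rng.random(n_steps) < cpg_density
    singles = rng.integers(0, 4, size=n_steps)
    parts = np.where(plant, 4, singles)  # 4 encodes the CG pair
    lengths = np.where(plant, 2, 1)
    keep = np.cumsum(lengths) <= length
    parts, plant = parts[keep], plant[keep]
    chars: list[str] = []
    for code in parts:
        chars.append("CG" if code == 4 else "ACGT"[code])
    seq = list("".join(chars))
    # pad to exact length with non-C/G-forming bases
    while len(seq) < length:
        seq.append("A" if (seq and seq[-1] == "C") else "T")
    seq = seq[:length]
    planted_starts = set()
    i = 0
    for code, ln in zip(parts, np.where(plant, 2, 1)):
        if code == 4:
            planted_starts.add(i)
        i += ln
    for j in range(1, length):
        if seq[j] == "G" and seq[j - 1] == "C" and (j - 1) not in planted_starts:
            seq[j] = "A"
    return "".join(seq)


def build_cytosine_map(seqs: dict) -> CytosineMap:
    """Locate every C (+ strand) and G (- strand) with a defined context;
    classification matches ``calling.classify_context`` by construction
    (and is cross-checked in the test suite)."""
    chrom_order = list(seqs)
    chroms, positions, strands, contexts = [], [], [], []
    for chrom in chrom_order:
        seq = seqs[chrom].upper()
        arr = np.frombuffer(seq.encode(), dtype="S1")
        n = len(seq)
        for strand, base in (("+", b"C"), ("-", b"G")):
            idx = np.flatnonzero(arr == base)
            for i in idx:
                try:
                    ctx = classify_context(seq, int(i), strand)
                except (ValueError, IndexError):
                    ctx = None
                if ctx is None:
                    continue
                chroms.append(chrom)
                positions.append(int(i) + 1)
                strands.append(strand)
                contexts.append(ctx)
    order = np.lexsort((np.array(positions), np.array(chroms)))
    return CytosineMap(
        chrom_order,
        np.array(chroms, dtype=object)[order],
        np.array(positions, dtype=int)[order],
        np.array(strands, dtype=object)[order],
        np.array(contexts, dtype=object)[order],
    )


# ---------------------------------------------------------------------------
# truth planting


def sample_baseline_rates(n: int, rng) -> np.ndarray:
    """Bimodal CpG methylation baseline: 70% high (Beta(9,1)), 20% low
    (Beta(1,9)), 10% intermediate (Uniform)."""
    mix = rng.random(n)
    out = np.empty(n)
    hi = mix < 0.7
    lo = (mix >= 0.7) & (mix < 0.9)
    mid = mix >= 0.9
    out[hi] = rng.beta(9, 1, hi.sum())
    out[lo] = rng.beta(1, 9, lo.sum())
    out[mid] = rng.random(mid.sum())
    return out


def plant_truth(
    cyt_map: CytosineMap,
    n_dmrs: int = 20,
    dmr_n_cpg: int = 10,
    delta: float = 0.5,
    dispersion: float = 0.1,
    seed: int = 0,
    alternate_sign: bool = True,
) -> SimulationTruth:
    """Choose non-overlapping runs of ``dmr_n_cpg`` consecutive cytosines
    as planted DMRs and build the per-position true group rates.

    DMR baselines are redrawn uniformly from [|delta|/2, 1 - |delta|/2]
    so the +/- delta/2 group shift never clips.
    """
    rng = np.random.default_rng(seed)
    n = len(cyt_map)
    baseline = sample_baseline_rates(n, rng)
    g1 = baseline.copy()
    g2 = baseline.copy()
    planted: list[PlantedDMR] = []
    if n_dmrs > 0:
        if n < n_dmrs * dmr_n_cpg * 3:
            raise ValueError("cytosine map too small for the requested DMRs")
        taken = np.zeros(n, dtype=bool)
        attempts = 0
        while len(planted) < n_dmrs and attempts < 10_000:
            attempts += 1
            lo = int(rng.integers(0, n - dmr_n_cpg))
            hi = lo + dmr_n_cpg - 1
            # pad by one window on each side to keep planted DMRs separated
            pad_lo = max(lo - dmr_n_cpg, 0)
            pad_hi = min(hi + dmr_n_cpg, n - 1)
            if taken[pad_lo : pad_hi + 1].any():
                continue
            if cyt_map.chroms[lo] != cyt_map.chroms[hi]:
                continue
            taken[pad_lo : pad_hi + 1] = True
            d = delta if (not alternate_sign or len(planted) % 2 == 0) else -delta
            base = rng.uniform(abs(d) / 2, 1 - abs(d) / 2, dmr_n_cpg)
            baseline[lo : hi + 1] = base
            g1[lo : hi + 1] = base + d / 2
            g2[lo : hi + 1] = base - d / 2
            planted.append(
                PlantedDMR(
                    chrom=str(cyt_map.chroms[lo]),
                    start=int(cyt_map.positions[lo]) - 1,
                    end=int(cyt_map.positions[hi]),
                    delta=d,
                    index_lo=lo,
                    index_hi=hi,
                )
            )
        if len(planted) < n_dmrs:
            raise RuntimeError("could not place the requested number of DMRs")
        planted.sort(key=lambda d: (d.chrom, d.start))
    np.clip(g1, 0.0, 1.0, out=g1)
    np.clip(g2, 0.0, 1.0, out=g2)
    return SimulationTruth(planted, baseline, g1, g2, dispersion)


# ---------------------------------------------------------------------------
# counts


def _beta_binomial(rng, cov: np.ndarray, rate: np.ndarray, dispersion: float):
    """n_meth ~ beta-binomial(cov, rate, dispersion); dispersion 0 is the
    pure binomial; rates of exactly 0/1 are point masses."""
    if dispersion <= 0:
        return rng.binomial(cov, rate)
    s = (1.0 - dispersion) / dispersion
    a = np.clip(rate, 0.0, 1.0) * s
    b = (1.0 - np.clip(rate, 0.0, 1.0)) * s
    p = np.empty_like(rate)
    interior = (a > 0) & (b > 0)
    p[interior] = rng.beta(a[interior], b[interior])
    p[~interior] = rate[~interior]
    return rng.binomial(cov, p)


def simulate_counts(
    cyt_map: CytosineMap,
    truth: SimulationTruth,
    n_per_group: int = 4,
    mean_coverage: float = 30.0,
    seed: int = 0,
) -> tuple[list, list, list]:
    """Per-sample methylation records for both groups.

    Returns (records_per_sample, sample_names, group_labels); positions
    with sampled coverage 0 are absent from that sample's records, as
    they would be from a real call set.
    """
    rng = np.random.default_rng(seed)
    n = len(cyt_map)
    all_records: list[list[MethylationRecord]] = []
    names: list[str] = []
    groups: list[str] = []
    for gi, rates in ((1, truth.rates_g1), (2, truth.rates_g2)):
        for si in range(n_per_group):
            cov = rng.poisson(mean_coverage, n)
            n_meth = _beta_binomial(rng, cov, rates, truth.dispersion)
            recs = [
                MethylationRecord(
                    str(cyt_map.chroms[i]),
                    int(cyt_map.positions[i]),
                    str(cyt_map.strands[i]),
                    str(cyt_map.contexts[i]),
                    int(n_meth[i]),
                    int(cov[i] - n_meth[i]),
                )
                for i in np.flatnonzero(cov > 0)
            ]
            all_records.append(recs)
            names.append(f"g{gi}_s{si + 1}")
            groups.append(f"group{gi}")
    return all_records, names, groups


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    seqs: dict,
    cyt_map: CytosineMap,
    true_rates: np.ndarray,
    out_bam,
    n_fragments: int = 2000,
    read_length: int = 80,
    fragment_length: int = 160,
    error_rate: float = 0.0,
    conversion_rate: float = 1.0,
    seed: int = 0,
) -> None:
    """Paired-end bisulfite reads as a sorted, indexed BAM.

    Each fragment derives from the original top (CT) or bottom (GA)
    strand with probability 1/2; every cytosine's methylation state is
    sampled once per fragment, so overlapping mates agree.  Unmethylated
    cytosines convert (C->T on CT fragments, read as G->A on GA) with
    probability ``conversion_rate``.  Sequencing errors are uniform
    substitutions, counted in the NM tag (conversions are not, matching
    bisulfite-aware aligners).  Reads carry the XG protocol-strand tag.
    """
    if not 0.9 < conversion_rate <= 1.0:
        raise ValueError("conversion_rate must be in (0.9, 1]")
    rng = np.random.default_rng(seed)
    chrom_order = list(seqs)
    lengths = np.array([len(seqs[c]) for c in chrom_order], dtype=float)
    if fragment_length > lengths.min():
        raise ValueError("fragments do not fit the reference")
    read_length = min(read_length, fragment_length)

    rate_lookup: dict[tuple[str, int], float] = {
        (str(c), int(p)): float(r)
        for c, p, r in zip(cyt_map.chroms, cyt_map.positions, true_rates)
    }

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(seqs[c])} for c in chrom_order],
    }
    reads = []
    probs = lengths / lengths.sum()
    for fi in range(n_fragments):
        ci = rng.choice(len(chrom_order), p=probs)
        chrom = chrom_order[ci]
        ref = seqs[chrom]
        start = int(rng.integers(0, len(ref) - fragment_length + 1))
        frag = list(ref[start : start + fragment_length].upper())
        bs_strand = "CT" if rng.random() < 0.5 else "GA"
        target, converted = ("C", "T") if bs_strand == "CT" else ("G", "A")
        for k, base in enumerate(frag):
            if base != target:
                continue
            rate = rate_lookup.get((chrom, start + k + 1), 0.0)
            methylated = rng.random() < rate
            if not methylated and rng.random() < conversion_rate:
                frag[k] = converted

        def with_errors(sub: list[str]) -> tuple[str, int]:
            nm = 0
            out = sub[:]
            if error_rate > 0:
                hits = np.flatnonzero(rng.random(len(sub)) < error_rate)
                for h in hits:
                    choices = [b for b in "ACGT" if b != out[h]]
                    out[h] = choices[int(rng.integers(0, 3))]
                    nm += 1
            return "".join(out), nm

        left_seq, left_nm = with_errors(frag[:read_length])
        right_raw, right_nm = with_errors(frag[fragment_length - read_length :])
        right_start = start + fragment_length - read_length
        # directional protocol: CT fragments sequence R1 from the left
        # forward; GA fragments sequence R1 from the right, reverse
        if bs_strand == "CT":
            r1 = (start, left_seq, False, left_nm)
            r2 = (right_start, right_raw, True, right_nm)
        else:
            r1 = (right_start, right_raw, True, right_nm)
            r2 = (start, left_seq, False, left_nm)
        reads.append((chrom, f"frag_{fi}", r1, r2, bs_strand))

    with pysam.AlignmentFile(str(out_bam) + ".unsorted.bam", "wb", header=header) as bam:
        for chrom, qname, r1, r2, bs_strand in reads:
            tid = chrom_order.index(chrom)
            segs = []
            for idx, (this, other) in enumerate(((r1, r2), (r2, r1))):
                a = pysam.AlignedSegment()
                a.query_name = qname
                a.query_sequence = this[1]
                a.reference_id = tid
                a.reference_start = this[0]
                a.mapping_quality = 60
                a.cigartuples = [(0, read_length)]
                a.next_reference_id = tid
                a.next_reference_start = other[0]
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                flag = 0x1 | 0x2  # paired, proper pair
                flag |= 0x40 if idx == 0 else 0x80
                if this[2]:
                    flag |= 0x10
                if other[2]:
                    flag |= 0x20
                a.flag = flag
                tlen = fragment_length if this[0] <= other[0] else -fragment_length
                a.template_length = tlen
                a.set_tag("NM", this[3])
                a.set_tag("XG", bs_strand)
                segs.append(a)
            for a in segs:
                bam.write(a)
    pysam.sort("-o", str(out_bam), str(out_bam) + ".unsorted.bam")
    Path(str(out_bam) + ".unsorted.bam").unlink()
    pysam.index(str(out_bam))


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    truth: SimulationTruth,
    dmr_methylation: pd.DataFrame,
    noise_sd: float = 0.5,
    n_unlinked_genes: int = 10,
    seed: int = 0,
    intercept: float = 5.0,
    slope: float = 4.0,
) -> tuple[pd.DataFrame, list]:
    """Expression table whose linked genes follow
    expression = intercept + sign * slope * methylation + N(0, noise_sd),
    clipped at 0 (with the default intercept/slope the clip never binds).

    ``dmr_methylation`` is a DMR x sample table of per-sample mean
    methylation over each planted DMR.  Returns (table, links) where
    links are (dmr_name, gene_id, sign) with alternating signs.
    """
    rng = np.random.default_rng(seed)
    samples = list(dmr_methylation.columns)
    rows = {}
    links = []
    for i, dmr_name in enumerate(dmr_methylation.index):
        gene = f"gene_{i + 1}"
        sign = 1 if i % 2 == 0 else -1
        meth = dmr_methylation.loc[dmr_name].to_numpy(dtype=float)
        expr = intercept + sign * slope * meth + rng.normal(0, noise_sd, len(samples))
        rows[gene] = np.clip(expr, 0.0, None)
        links.append((str(dmr_name), gene, sign))
    for j in range(n_unlinked_genes):
        rows[f"bg_gene_{j + 1}"] = rng.uniform(1.0, 9.0, len(samples))
    table = pd.DataFrame(rows, index=samples).T
    table.index.name = "gene_id"
    truth.expression_links = links
    return table, links


# ---------------------------------------------------------------------------
# one-call preset


def simulate_case_control(
    out_dir,
    seed: int = 0,
    n_chrom: int = 1,
    length: int = 255_000,
    cpg_density: float = 0.02,
    n_per_group: int = 4,
    mean_coverage: float = 30.0,
    dispersion: float = 0.1,
    n_dmrs: int = 20,
    dmr_n_cpg: int = 10,
    delta: float = 0.5,
    noise_sd: float = 0.5,
    write_reads: bool = False,
    n_fragments: int = 2000,
) -> dict:
    """Write a complete synthetic study to ``out_dir``: reference FASTA,
    per-sample methylation VCFs, truth JSON, expression and pair tables
    (and optionally a BAM for the calling stage).  Returns the manifest
    of written paths plus the in-memory truth objects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))

    seqs, cyt_map = simulate_reference(n_chrom, length, cpg_density, seed=sub())
    fasta = out_dir / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    cg = cyt_map.subset(cyt_map.contexts == "CG")
    truth = plant_truth(cg, n_dmrs, dmr_n_cpg, delta, dispersion, seed=sub())
    records, names, groups = simulate_counts(
        cg, truth, n_per_group, mean_coverage, seed=sub()
    )
    vcf_paths = {}
    for recs, name in zip(records, names):
        path = out_dir / f"{name}.vcf"
        write_methylation_vcf(recs, path)
        vcf_paths[name] = str(path)

    truth_json = out_dir / "truth.json"
    truth.to_json(truth_json, cg)

    # per-sample mean methylation over each planted DMR, from the truth
    # rates themselves (expression links are defined on the true signal)
    from .grouping import build_sample_matrix

    matrix = build_sample_matrix(records, names, min_coverage_per_sample=1)
    meth_rows = {}
    pos_index = {
        (str(c), int(p)): i
        for i, (c, p) in enumerate(
            (pos[0], pos[1]) for pos in matrix.positions
        )
    }
    for i, d in enumerate(truth.planted_dmrs):
        idx = [
            pos_index[(str(cg.chroms[k]), int(cg.positions[k]))]
            for k in range(d.index_lo, d.index_hi + 1)
            if (str(cg.chroms[k]), int(cg.positions[k])) in pos_index
        ]
        meth_rows[truth.dmr_name(i)] = np.nanmean(matrix.values[idx], axis=0)
    dmr_meth = pd.DataFrame(meth_rows, index=names).T
    expr, links = simulate_expression(
        truth, dmr_meth, noise_sd=noise_sd, seed=sub()
    )
    expr_path = out_dir / "expression.tsv"
    write_expression_table(expr, expr_path)
    pairs_path = out_dir / "pairs.tsv"
    write_pairs_table([(d, g) for d, g, _s in links], pairs_path)

    manifest = {
        "fasta": str(fasta),
        "samples": vcf_paths,
        "sample_names": names,
        "groups": groups,
        "truth": str(truth_json),
        "expression": str(expr_path),
        "pairs": str(pairs_path),
    }
    if write_reads:
        bam = out_dir / "sample_reads.bam"
        simulate_reads(
            seqs, cyt_map, _truth_rates_full(cyt_map, cg, truth),
            bam, n_fragments=n_fragments, seed=sub(),
        )
        manifest["bam"] = str(bam)
    manifest["_truth_obj"] = truth
    manifest["_cyt_map"] = cg
    manifest["_records"] = records
    return manifest


def _truth_rates_full(full_map: CytosineMap, cg_map: CytosineMap, truth: SimulationTruth):
    """Expand the CG-only baseline to all cytosines (non-CG contexts get
    the low non-CpG methylation typical outside plants, rate 0.02)."""
    rates = np.full(len(full_map), 0.02)
    cg_keys = {
        (str(c), int(p)): i for i, (c, p) in enumerate(zip(cg_map.chroms, cg_map.positions))
    }
    for i, (c, p) in enumerate(zip(full_map.chroms, full_map.positions)):
        j = cg_keys.get((str(c), int(p)))
        if j is not None:
            rates[i] = truth.baseline_rates[j]
    return rates
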