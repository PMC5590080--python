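"""Per-cytosine methylation calling from bisulfite-aligned reads.

Bisulfite treatment converts unmethylated cytosines to uracil (sequenced
as T) while methylated cytosines stay C.  A read therefore reports the
methylation state of the reference cytosines it covers: on the original
top strand (C->T converted, "CT" reads) a C at a reference C means
methylated and a T means unmethylated; on the original bottom strand
("GA" reads) the same information appears at reference G positions as
G (methylated) versus A (unmethylated).

The caller walks fragments rather than pileup columns so that the
overlapping portion of a properly-paired fragment can be counted once:
within an overlap the base with the higher quality wins, ties go to
read 1.  End-trimming (a blunt M-bias mitigation) and base/mapping
quality thresholds are applied per base.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pysam

from .io import MethylationRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CallingOptions:
    min_base_quality: int = 20
    min_mapping_quality: int = 10
    trim_ends: int = 0
    clip_overlap: bool = True
    contexts_emitted: frozenset = frozenset({"CG", "CHG", "CHH"})

    def __post_init__(self):
        if self.min_base_quality < 0 or self.min_mapping_quality < 0 or self.trim_ends < 0:
            raise ValueError("thresholds must be non-negative")
        self.contexts_emitted = frozenset(self.contexts_emitted)
        unknown = self.contexts_emitted - {"CG", "CHG", "CHH"}
        if unknown:
            raise ValueError(f"unknown contexts: {sorted(unknown)}")


@dataclass
class MappingStats:
    n_reads_total: int = 0
    n_mapped: int = 0
    n_pairs_mapped: int = 0
    fraction_mapped: float = 0.0
    multiplicity_histogram: dict = field(default_factory=dict)
    mean_error_rate: float = 0.0
    empty_input: bool = False


def classify_context(ref_seq: str, pos: int, strand: str) -> str | None:
    """Classify the cytosine at ``pos`` (0-based) into CG / CHG / CHH.

    The context is read in 5'->3' direction of the cytosine's own strand:
    on ``+`` the two bases following ``pos``; on ``-`` the complements of
    the two bases preceding it.  Returns None when the window runs off the
    sequence end or contains an ambiguous base.
    """
    n = len(ref_seq)
    if pos < 0 or pos >= n:
        raise IndexError(f"position {pos} outside sequence of length {n}")
    base = ref_seq[pos].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"expected C at + strand position {pos}, found {base}")
        window = ref_seq[pos + 1 : pos + 3].upper()
    elif strand == "-":
        if base != "G":
            raise ValueError(f"expected G at - strand position {pos}, found {base}")
        window = ref_seq[max(pos - 2, 0) : pos].upper()[::-1].translate(_COMPLEMENT)
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if len(window) < 2 or "N" in window:
        return None
    if window[0] == "G":
        return "CG"
    if window[1] == "G":
        return "CHG"
    return "CHH"


def _bisulfite_strand(read: pysam.AlignedSegment) -> str:
    """Protocol strand of a read: 'CT' (original top) or 'GA' (bottom).

    Prefers the aligner's XG tag (Bismark convention); falls back to the
    directional-protocol inference from read orientation: read 1 forward
    and read 2 reverse sequence the C->T converted strand.
    """
    if read.has_tag("XG"):
        tag = read.get_tag("XG")
        if tag in ("CT", "GA"):
            return tag
    reverse = read.is_reverse
    if read.is_paired and read.is_read2:
        reverse = not reverse
    return "GA" if reverse else "CT"


def _read_contributions(read: pysam.AlignedSegment, ref_seq: str, opts: CallingOptions):
    """Yield (ref_pos, call, base_quality) per usable cytosine base.

    ``call`` is 1 (methylated), 0 (unmethylated) or None (uninformative
    base, still occupying the position for overlap resolution).  Deleted
    and soft-clipped bases never appear; insertions have no ref_pos.
    """
    bs_strand = _bisulfite_strand(read)
    seq = read.query_sequence
    quals = read.query_qualities
    qlen = read.query_length
    lo, hi = opts.trim_ends, qlen - opts.trim_ends
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if not (lo <= qpos < hi):
            continue
        bq = quals[qpos]
        if bq < opts.min_base_quality:
            continue
        ref_base = ref_seq[rpos]
        base = seq[qpos].upper()
        call = None
        if bs_strand == "CT" and ref_base == "C":
            call = 1 if base == "C" else (0 if base == "T" else None)
        elif bs_strand == "GA" and ref_base == "G":
            call = 1 if base == "G" else (0 if base == "A" else None)
        else:
            continue
        yield rpos, call, bq


def _resolve_overlap(contribs_r1, contribs_r2):
    """Merge two mates' per-position contributions, counting overlap once.

    Higher base quality wins; on a tie read 1 wins.
    """
    merged = dict(contribs_r2)
    for rpos, (call, bq) in contribs_r1.items():
        if rpos in merged and merged[rpos][1] > bq:
            continue
        merged[rpos] = (call, bq)
    return merged


def call_methylation(
    bam_path,
    reference,
    opts: CallingOptions | None = None,
    contigs: list[str] | None = None,
) -> list[MethylationRecord]:
    """Call per-cytosine methylation from a sorted, indexed BAM.

    ``reference`` is a pyfaidx.Fasta (or any mapping of contig name to
    sliceable sequence).  Returns records sorted by (chrom, pos), one per
    covered cytosine whose context is in ``opts.contexts_emitted``.
    """
    opts = opts or CallingOptions()
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path} is not indexed (run samtools index)")
        bam_contigs = list(bam.references)
        todo = contigs if contigs is not None else bam_contigs
        ref_names = set(_reference_names(reference))
        records: list[MethylationRecord] = []
        for contig in todo:
            if contig not in ref_names:
                raise ValueError(f"contig {contig!r} missing from the reference FASTA")
            if contig not in bam_contigs:
                raise ValueError(f"contig {contig!r} missing from the BAM header")
            ref_seq = str(reference[contig][:]).upper()
            records.extend(_call_contig(bam, contig, ref_seq, opts))
    records.sort(key=MethylationRecord.sort_key)
    return records


def _reference_names(reference):
    if hasattr(reference, "keys"):
        return list(reference.keys())
    return list(reference)


def _usable(read: pysam.AlignedSegment, opts: CallingOptions) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
        or read.mapping_quality < opts.min_mapping_quality
    )


def _call_contig(bam, contig, ref_seq, opts: CallingOptions):
    # counts[(rpos, strand)] = [n_meth, n_unmeth]
    counts: dict[tuple[int, str], list[int]] = defaultdict(lambda: [0, 0])
    pending: dict[str, dict] = {}  # qname -> first mate's contributions

    def tally(contribs):
        for rpos, (call, _bq) in contribs.items():
            if call is None:
                continue
            strand = "+" if ref_seq[rpos] == "C" else "-"
            counts[(rpos, strand)][0 if call else 1] += 1

    last_pos = -1
    for read in bam.fetch(contig):
        if read.reference_start < last_pos:
            raise ValueError(f"{contig}: alignments not coordinate-sorted")
        last_pos = read.reference_start
        if not _usable(read, opts):
            continue
        contribs = {
            rpos: (call, bq) for rpos, call, bq in _read_contributions(read, ref_seq, opts)
        }
        overlapping_pair = (
            opts.clip_overlap
            and read.is_proper_pair
            and read.reference_name == read.next_reference_name
        )
        if not overlapping_pair:
            tally(contribs)
            continue
        if read.query_name in pending:
            first = pending.pop(read.query_name)
            if read.is_read1:
                merged = _resolve_overlap(contribs, first)
            else:
                merged = _resolve_overlap(first, contribs)
            tally(merged)
        else:
            pending[read.query_name] = contribs
    # mates that never showed up (off-contig or filtered) count alone
    for contribs in pending.values():
        tally(contribs)

    for (rpos, strand), (nm, nu) in sorted(counts.items()):
        ctx = classify_context(ref_seq, rpos, strand)
        if ctx is None or ctx not in opts.contexts_emitted:
            continue
        yield MethylationRecord(contig, rpos + 1, strand, ctx, nm, nu)


def mapping_statistics(bam_path) -> MappingStats:
    """Alignment QC: mapped fraction, alignment multiplicity, error rate.

    The error rate is the aligner's mismatch count (NM tag) divided by
    aligned (M/=/X) bases, over primary mapped reads carrying the tag.
    """
    stats = MappingStats()
    multiplicity: dict[tuple[str, bool], int] = defaultdict(int)
    mapped_primary: set[tuple[str, bool]] = set()
    all_reads: set[tuple[str, bool]] = set()
    pair_mates_mapped: dict[str, set[bool]] = defaultdict(set)
    nm_sum = 0
    aligned_bases = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(until_eof=True):
            key = (read.query_name, read.is_read2)
            all_reads.add(key)
            if read.is_unmapped:
                continue
            multiplicity[key] += 1
            if read.is_secondary or read.is_supplementary:
                continue
            mapped_primary.add(key)
            if read.is_paired and read.is_proper_pair:
                pair_mates_mapped[read.query_name].add(read.is_read2)
            if read.has_tag("NM"):
                nm_sum += read.get_tag("NM")
                aligned_bases += sum(
                    length
                    for op, length in (read.cigartuples or [])
                    if op in (0, 7, 8)  # M, =, X
                )
    stats.n_reads_total = len(all_reads)
    stats.n_mapped = len(mapped_primary)
    stats.n_pairs_mapped = sum(1 for mates in pair_mates_mapped.values() if len(mates) == 2)
    if stats.n_reads_total == 0:
        stats.empty_input = True
    else:
        stats.fraction_mapped = stats.n_mapped / stats.n_reads_total
    hist: dict[int, int] = defaultdict(int)
    for n_aln in multiplicity.values():
        hist[n_aln] += 1
    stats.multiplicity_histogram = dict(sorted(hist.items()))
    stats.mean_error_rate = nm_sum / aligned_bases if aligned_bases else 0.0
    return stats
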