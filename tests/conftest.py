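"""Shared fixtures: tiny references, BAM builders, record factories."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from methtk.io import MethylationRecord


@pytest.fixture
def make_bam(tmp_path):
    """Build a sorted, indexed BAM from explicit read dicts.

    Each read dict: qname, flag, pos (0-based), cigar (string), seq,
    and optional quals (string), mapq, tags (dict), rnext/pnext/tlen.
    """

    def _make(reference: dict[str, str], reads: list[dict], name="fixture.bam"):
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.items()],
        }
        chrom_order = list(reference)
        path = tmp_path / name
        unsorted = tmp_path / ("unsorted_" + name)
        with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
            for rd in reads:
                a = pysam.AlignedSegment()
                a.query_name = rd["qname"]
                a.flag = rd.get("flag", 0)
                a.reference_id = chrom_order.index(rd.get("chrom", chrom_order[0]))
                a.reference_start = rd["pos"]
                a.mapping_quality = rd.get("mapq", 60)
                a.cigarstring = rd["cigar"]
                a.query_sequence = rd["seq"]
                quals = rd.get("quals", "I" * len(rd["seq"]))
                a.query_qualities = pysam.qualitystring_to_array(quals)
                if "pnext" in rd:
                    a.next_reference_id = a.reference_id
                    a.next_reference_start = rd["pnext"]
                    a.template_length = rd.get("tlen", 0)
                for tag, value in rd.get("tags", {}).items():
                    a.set_tag(tag, value)
                bam.write(a)
        pysam.sort("-o", str(path), str(unsorted))
        pysam.index(str(path))
        return path

    return _make


def brute_force_pileup(bam_path, reference: dict[str, str], opts):
    """Independent per-base pileup: walks each read's CIGAR by hand and
    resolves mate overlaps per fragment.  Returns {(chrom, pos0, strand):
    [n_meth, n_unmeth]} under the same contract as the caller."""
    per_fragment: dict[tuple, dict] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.is_qcfail
                or read.mapping_quality < opts.min_mapping_quality
            ):
                continue
            if read.has_tag("XG"):
                bs = read.get_tag("XG")
            else:
                rev = read.is_reverse
                if read.is_paired and read.is_read2:
                    rev = not rev
                bs = "GA" if rev else "CT"
            chrom = read.reference_name
            ref_seq = reference[chrom].upper()
            qpos, rpos = 0, read.reference_start
            contribs = {}
            for op, length in read.cigartuples:
                if op in (0, 7, 8):  # aligned
                    for k in range(length):
                        q, r = qpos + k, rpos + k
                        if not (opts.trim_ends <= q < read.query_length - opts.trim_ends):
                            continue
                        if read.query_qualities[q] < opts.min_base_quality:
                            continue
                        base = read.query_sequence[q].upper()
                        refb = ref_seq[r]
                        if bs == "CT" and refb == "C":
                            call = {"C": 1, "T": 0}.get(base)
                        elif bs == "GA" and refb == "G":
                            call = {"G": 1, "A": 0}.get(base)
                        else:
                            continue
                        contribs[r] = (call, read.query_qualities[q], read.is_read1)
                    qpos += length
                    rpos += length
                elif op in (1, 4):  # insertion, soft clip consume query
                    qpos += length
                elif op in (2, 3):  # deletion, ref skip consume reference
                    rpos += length
            in_pair = (
                opts.clip_overlap
                and read.is_proper_pair
                and read.reference_name == read.next_reference_name
            )
            frag_key = (chrom, read.query_name) if in_pair else (chrom, read.query_name, read.is_read2, read.reference_start)
            slot = per_fragment.setdefault(frag_key, {})
            for r, (call, bq, is_r1) in contribs.items():
                if r in slot:
                    old_call, old_bq, old_r1 = slot[r]
                    if old_bq > bq or (old_bq == bq and old_r1):
                        continue
                slot[r] = (call, bq, is_r1)
    counts: dict[tuple, list] = {}
    for (chrom, *_rest), contribs in per_fragment.items():
        ref_seq = reference[chrom].upper()
        for r, (call, _bq, _r1) in contribs.items():
            if call is None:
                continue
            strand = "+" if ref_seq[r] == "C" else "-"
            key = (chrom, r, strand)
            counts.setdefault(key, [0, 0])[0 if call else 1] += 1
    return counts


def records_to_count_dict(records):
    return {(r.chrom, r.pos - 1, r.strand): [r.n_meth, r.n_unmeth] for r in records}


def make_records(chrom="chr1", start=101, step=10, rates=(), coverage=20, context="CG"):
    """Evenly spaced records with prescribed rates at fixed coverage."""
    out = []
    for i, rate in enumerate(rates):
        n_meth = round(rate * coverage)
        out.append(
            MethylationRecord(chrom, start + i * step, "+", context, n_meth, coverage - n_meth)
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
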