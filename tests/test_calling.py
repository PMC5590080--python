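"""Context classification and methylation calling against an
independent brute-force pileup oracle."""

import pytest

from methtk.calling import (
    CallingOptions,
    call_methylation,
    classify_context,
    mapping_statistics,
)

from conftest import brute_force_pileup, records_to_count_dict

# 60 bp reference with CpGs at 0-based 3, 13, 23, 33, 43 (C on +, G on -)
REF = "ATTCGTTATTATTCGTTATTATTCGTTATTATTCGTTATTATTCGTTATTATTAACCTT"
REFERENCE = {"chr1": REF}
LAX = CallingOptions(min_base_quality=0, min_mapping_quality=0)


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 1, "+", "CG"),
            ("ACAGT", 1, "+", "CHG"),
            ("ACATT", 1, "+", "CHH"),
            ("ACGT", 2, "-", "CG"),  # reverse-complement reading: C then G
            ("CCAGG", 3, "-", "CHG"),
            ("TTGAA", 2, "-", "CHH"),
        ],
    )
    def test_contexts(self, seq, pos, strand, expected):
        assert classify_context(seq, pos, strand) == expected

    def test_window_off_the_end_is_undeterminable(self):
        assert classify_context("ATC", 2, "+") is None
        assert classify_context("GAT", 0, "-") is None

    def test_ambiguous_base_gives_none(self):
        assert classify_context("ACNG", 1, "+") is None

    def test_wrong_base_raises(self):
        with pytest.raises(ValueError):
            classify_context("AAAA", 1, "+")
        with pytest.raises(IndexError):
            classify_context("ACGT", 9, "+")

    def test_strand_symmetry_of_cpg(self):
        # both strands of a CpG classify as CG
        seq = "TTACGTT"
        assert classify_context(seq, 3, "+") == "CG"
        assert classify_context(seq, 4, "-") == "CG"


def _read(qname, pos, seq, flag=0, cigar=None, **kw):
    return dict(qname=qname, pos=pos, seq=seq, flag=flag, cigar=cigar or f"{len(seq)}M", **kw)


class TestCallMethylation:
    def test_empty_bam_empty_output(self, make_bam):
        bam = make_bam(REFERENCE, [])
        assert call_methylation(bam, REFERENCE, LAX) == []

    def test_single_unconverted_read_is_fully_methylated(self, make_bam):
        # read matches the reference exactly: the CpG C stayed C
        bam = make_bam(REFERENCE, [_read("r1", 0, "ATTCGTT")])
        records = call_methylation(bam, REFERENCE, LAX)
        cg = [r for r in records if r.context == "CG"]
        assert len(cg) == 1
        assert (cg[0].pos, cg[0].strand, cg[0].n_meth, cg[0].n_unmeth) == (4, "+", 1, 0)
        assert cg[0].rate == 1.0

    def test_converted_read_is_unmethylated(self, make_bam):
        bam = make_bam(REFERENCE, [_read("r1", 0, "ATTTGTT")])  # C->T at the CpG
        records = call_methylation(bam, REFERENCE, LAX)
        cg = [r for r in records if r.context == "CG"]
        assert (cg[0].n_meth, cg[0].n_unmeth) == (0, 1)

    def test_reverse_strand_read_reports_minus_cytosine(self, make_bam):
        # GA-protocol read covering the G at 0-based 4: A = converted
        bam = make_bam(
            REFERENCE,
            [_read("r1", 0, "ATTCATT", flag=16, tags={"XG": "GA"})],
        )
        records = call_methylation(bam, REFERENCE, LAX)
        minus = [r for r in records if r.strand == "-"]
        assert len(minus) == 1
        assert (minus[0].pos, minus[0].n_meth, minus[0].n_unmeth) == (5, 0, 1)

    def test_overlapping_pair_counts_each_position_once(self, make_bam):
        # proper pair, both mates span the CpG at 0-based 13
        reads = [
            _read("p1", 8, "TTATTCGTTAT", flag=0x1 | 0x2 | 0x40, pnext=10, tlen=13,
                  tags={"XG": "CT"}),
            _read("p1", 10, "ATTCGTTATTA", flag=0x1 | 0x2 | 0x80 | 0x10, pnext=8,
                  tlen=-13, tags={"XG": "CT"}),
        ]
        bam = make_bam(REFERENCE, reads)
        records = call_methylation(bam, REFERENCE, LAX)
        at_cpg = [r for r in records if r.pos == 14 and r.strand == "+"]
        assert at_cpg[0].coverage == 1  # not 2

    def test_overlap_tie_goes_to_higher_quality(self, make_bam):
        # mates disagree at the CpG: read2 carries the higher-quality base
        reads = [
            _read("p1", 8, "TTATTCGTTAT", flag=0x1 | 0x2 | 0x40, pnext=10, tlen=13,
                  quals="!" * 11, tags={"XG": "CT"}),
            _read("p1", 10, "ATTTGTTATTA", flag=0x1 | 0x2 | 0x80 | 0x10, pnext=8,
                  tlen=-13, quals="I" * 11, tags={"XG": "CT"}),
        ]
        bam = make_bam(REFERENCE, reads)
        records = call_methylation(bam, REFERENCE, LAX)
        at_cpg = [r for r in records if r.pos == 14 and r.strand == "+"][0]
        assert (at_cpg.n_meth, at_cpg.n_unmeth) == (0, 1)

    def test_no_clip_overlap_counts_twice(self, make_bam):
        reads = [
            _read("p1", 8, "TTATTCGTTAT", flag=0x1 | 0x2 | 0x40, pnext=10, tlen=13,
                  tags={"XG": "CT"}),
            _read("p1", 10, "ATTCGTTATTA", flag=0x1 | 0x2 | 0x80 | 0x10, pnext=8,
                  tlen=-13, tags={"XG": "CT"}),
        ]
        bam = make_bam(REFERENCE, reads)
        opts = CallingOptions(min_base_quality=0, min_mapping_quality=0, clip_overlap=False)
        records = call_methylation(bam, REFERENCE, opts)
        at_cpg = [r for r in records if r.pos == 14 and r.strand == "+"][0]
        assert at_cpg.coverage == 2

    def test_deletion_and_soft_clip_contribute_nothing(self, make_bam):
        # 4M2D3M deletes ref 4..5 (the G of the CpG and the next T);
        # soft-clipped prefix must be ignored
        reads = [
            _read("r1", 0, "TTATTCTTA", cigar="2S4M2D3M"),
        ]
        bam = make_bam(REFERENCE, reads)
        records = call_methylation(bam, REFERENCE, LAX)
        assert [r.pos for r in records if r.strand == "+"] == [4]

    def test_secondary_and_duplicate_skipped(self, make_bam):
        reads = [
            _read("r1", 0, "ATTCGTT"),
            _read("r1", 0, "ATTCGTT", flag=0x100),
            _read("r2", 0, "ATTCGTT", flag=0x400),
        ]
        bam = make_bam(REFERENCE, reads)
        records = call_methylation(bam, REFERENCE, LAX)
        at_cpg = [r for r in records if r.pos == 4][0]
        assert at_cpg.coverage == 1

    def test_context_restriction_equals_posthoc_filter(self, make_bam):
        reads = [_read("r1", 30, REF[30:55])]
        bam = make_bam(REFERENCE, reads)
        full = call_methylation(bam, REFERENCE, LAX)
        cg_only = call_methylation(
            bam,
            REFERENCE,
            CallingOptions(min_base_quality=0, min_mapping_quality=0,
                           contexts_emitted={"CG"}),
        )
        assert cg_only == [r for r in full if r.context == "CG"]

    def test_contig_mismatch_raises(self, make_bam):
        bam = make_bam(REFERENCE, [_read("r1", 0, "ATTCGTT")])
        with pytest.raises(ValueError, match="chr1"):
            call_methylation(bam, {"chr9": REF}, LAX)

    @pytest.mark.parametrize(
        "fixture_name,reads",
        [
            ("mixed_strands", [
                _read("a", 0, "ATTCGTTATT"),
                _read("b", 0, "ATTTGTTATT"),
                _read("c", 1, "TTCATTATTA", flag=16, tags={"XG": "GA"}),
                _read("d", 10, "ATTCGTTATT"),
                _read("e", 10, "ATTCGTTATT", flag=16, tags={"XG": "GA"}),
            ]),
            ("overlapping_pairs", [
                _read("p1", 8, "TTATTCGTTAT", flag=0x1 | 0x2 | 0x40, pnext=10,
                      tlen=13, tags={"XG": "CT"}),
                _read("p1", 10, "ATTCGTTATTA", flag=0x1 | 0x2 | 0x80 | 0x10,
                      pnext=8, tlen=-13, tags={"XG": "CT"}),
                _read("p2", 20, "TTCGTTATT", flag=0x1 | 0x2 | 0x40, pnext=22,
                      tlen=11, tags={"XG": "CT"}),
                _read("p2", 22, "TGTTATTAT", flag=0x1 | 0x2 | 0x80 | 0x10,
                      pnext=20, tlen=-11, tags={"XG": "CT"}),
            ]),
            ("indels_and_clips", [
                _read("i1", 0, "ATTCGGGTTATT", cigar="5M3I4M"),
                _read("i2", 10, "ATTCTTATT", cigar="4M2D5M"),
                _read("i3", 20, "AATTCGTTA", cigar="2S7M"),
                _read("i4", 40, "TTCGTT", cigar="6M"),
            ]),
            ("quality_mix", [
                _read("q1", 0, "ATTCGTTATT", quals="IIII!IIIII"),
                _read("q2", 0, "ATTTGTTATT", quals="III!IIIIII"),
                _read("q3", 12, "TCGTTATT", quals="I" * 8),
            ]),
            ("multi_cpg_spans", [
                _read("m1", 0, REF[0:35].replace("CG", "TG")),  # all converted
                _read("m2", 20, REF[20:50]),  # all methylated
                _read("m3", 5, REF[5:40], flag=16, tags={"XG": "GA"}),
            ]),
        ],
    )
    def test_counts_equal_brute_force_oracle(self, make_bam, fixture_name, reads):
        bam = make_bam(REFERENCE, reads, name=f"{fixture_name}.bam")
        opts = CallingOptions(min_base_quality=20, min_mapping_quality=0)
        records = call_methylation(bam, REFERENCE, opts)
        oracle = brute_force_pileup(bam, REFERENCE, opts)
        # the caller only emits positions with a classifiable context,
        # and only counts informative bases
        oracle = {
            k: v for k, v in oracle.items() if v != [0, 0]
        }
        called = records_to_count_dict(records)
        for key in oracle:
            assert called.get(key, [0, 0]) == oracle[key], (fixture_name, key)
        for key in called:
            assert called[key] == oracle.get(key, [0, 0]), (fixture_name, key)

    def test_determinism(self, make_bam):
        reads = [_read(f"r{i}", i, REF[i : i + 12]) for i in range(0, 30, 3)]
        bam = make_bam(REFERENCE, reads)
        a = call_methylation(bam, REFERENCE, LAX)
        b = call_methylation(bam, REFERENCE, LAX)
        assert a == b


class TestMappingStatistics:
    def test_all_mapped_no_errors(self, make_bam):
        reads = [_read(f"r{i}", i, REF[i : i + 10], tags={"NM": 0}) for i in range(10)]
        bam = make_bam(REFERENCE, reads)
        stats = mapping_statistics(bam)
        assert stats.n_reads_total == 10
        assert stats.fraction_mapped == 1.0
        assert stats.mean_error_rate == 0.0
        assert stats.multiplicity_histogram == {1: 10}

    def test_empty_bam_flagged(self, make_bam):
        bam = make_bam(REFERENCE, [])
        stats = mapping_statistics(bam)
        assert stats.n_reads_total == 0
        assert stats.fraction_mapped == 0.0
        assert stats.empty_input

    def test_counts_equal_brute_force_recount(self, make_bam, rng):
        reads = []
        n_mapped = 0
        nm_total = 0
        aligned = 0
        for i in range(100):
            if i < 80:
                nm = int(rng.integers(0, 3))
                length = 10
                reads.append(
                    _read(f"r{i}", int(rng.integers(0, 40)), "A" * length, tags={"NM": nm})
                )
                n_mapped += 1
                nm_total += nm
                aligned += length
            else:
                reads.append(_read(f"r{i}", 0, "A" * 10, flag=0x4))
        bam = make_bam(REFERENCE, reads)
        stats = mapping_statistics(bam)
        assert stats.n_reads_total == 100
        assert stats.n_mapped == 80
        assert stats.fraction_mapped == pytest.approx(0.8)
        assert stats.mean_error_rate == pytest.approx(nm_total / aligned)

    def test_multiplicity_counts_secondary_alignments(self, make_bam):
        reads = [
            _read("r1", 0, "ATTCGTT"),
            _read("r1", 10, "ATTCGTT", flag=0x100),
            _read("r2", 0, "ATTCGTT"),
        ]
        bam = make_bam(REFERENCE, reads)
        stats = mapping_statistics(bam)
        assert stats.multiplicity_histogram == {1: 1, 2: 1}
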