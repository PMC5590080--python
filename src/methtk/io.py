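"""Core domain types and on-disk formats.

The pipeline speaks a small set of plain-text formats:

* a minimal VCF-style dialect for per-cytosine methylation calls
  (``CHROM POS ID REF ALT QUAL FILTER INFO`` with counts in INFO),
* bedGraph for browser tracks (0-based half-open),
* BED 3/4/6 for annotation regions,
* TSV for expression tables and DMR-gene pair lists.

All interval types are 0-based half-open internally; VCF-dialect positions
are 1-based.  Readers recompute derived quantities (the methylation rate)
from the stored counts rather than trusting the file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

VCF_HEADER = (
    "##fileformat=VCFv4.2-methylation-dialect\n"
    '##INFO=<ID=CS,Number=1,Type=String,Description="Cytosine strand">\n'
    '##INFO=<ID=CC,Number=1,Type=String,Description="Cytosine context">\n'
    '##INFO=<ID=NM,Number=1,Type=Integer,Description="Reads supporting methylation">\n'
    '##INFO=<ID=NU,Number=1,Type=Integer,Description="Reads supporting non-methylation">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class MethylationRecord:
    """One reference cytosine with methylated/unmethylated read counts.

    ``pos`` is the 1-based position of the cytosine on the forward
    reference strand; a ``-`` strand record refers to a G on the forward
    sequence (the cytosine of the reverse complement).
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def rate(self) -> float:
        """Methylation level n_meth / coverage; NaN when coverage is 0."""
        cov = self.coverage
        return self.n_meth / cov if cov > 0 else float("nan")

    def sort_key(self):
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class AnnotationItem:
    """A named genomic interval, 0-based half-open (BED semantics)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region between two sample groups."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    n_cpg: int
    mean_g1: float
    mean_g2: float
    p_mwu: float
    p_ks2d: float
    q: float
    name: str = ""

    def __post_init__(self):
        if self.n_cpg < 2:
            raise ValueError("a DMR spans at least 2 tested positions")
        if self.start >= self.end:
            raise ValueError("DMR interval must be non-empty")

    @property
    def mean_diff(self) -> float:
        return self.mean_g1 - self.mean_g2

    @property
    def direction(self) -> str:
        """'hyper' when group 1 is more methylated, else 'hypo'."""
        return "hyper" if self.mean_diff > 0 else "hypo"

    @property
    def length_nt(self) -> int:
        return self.end - self.start


class SampleMatrix:
    """Positions x samples methylation-rate matrix.

    Missing entries (coverage below the build threshold, or position not
    called in a sample) are NaN in ``values`` and 0 in ``coverages``;
    a rate of 0 is biologically meaningful and is never used to encode
    missingness.
    """

    def __init__(
        self,
        positions: Sequence[tuple],
        sample_names: Sequence[str],
        values: np.ndarray,
        coverages: np.ndarray,
    ):
        self.positions = list(positions)  # (chrom, pos, strand, context)
        self.sample_names = list(sample_names)
        self.values = np.asarray(values, dtype=float)
        self.coverages = np.asarray(coverages, dtype=int)
        n, s = len(self.positions), len(self.sample_names)
        if self.values.shape != (n, s) or self.coverages.shape != (n, s):
            raise ValueError("matrix dimensions inconsistent with positions/samples")
        if len(set(self.sample_names)) != s:
            raise ValueError("duplicate sample names")
        ok = np.isnan(self.values) | ((self.values >= 0) & (self.values <= 1))
        if not ok.all():
            raise ValueError("rates must lie in [0, 1] or be missing")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def sample_index(self, name: str) -> int:
        try:
            return self.sample_names.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(
            self.positions, names=["chrom", "pos", "strand", "context"]
        )
        return pd.DataFrame(self.values, index=idx, columns=self.sample_names)


@dataclass
class GroupSummary:
    """Per-position group means and their difference (group1 - group2)."""

    positions: list  # (chrom, pos, strand, context)
    mean_g1: np.ndarray
    mean_g2: np.ndarray
    n_covered_g1: np.ndarray
    n_covered_g2: np.ndarray
    group1: list = field(default_factory=list)
    group2: list = field(default_factory=list)

    @property
    def diff(self) -> np.ndarray:
        return self.mean_g1 - self.mean_g2

    def __len__(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# methylation VCF dialect


def _record_to_vcf_line(rec: MethylationRecord) -> str:
    ref = "C" if rec.strand == "+" else "G"
    info = f"CS={rec.strand};CC={rec.context};NM={rec.n_meth};NU={rec.n_unmeth}"
    return f"{rec.chrom}\t{rec.pos}\t.\t{ref}\t.\t.\tPASS\t{info}\n"


def write_methylation_vcf(records: Iterable[MethylationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for rec in records:
            fh.write(_record_to_vcf_line(rec))


def read_methylation_vcf(path) -> list[MethylationRecord]:
    """Read the methylation VCF dialect; rates are recomputed from counts."""
    records: list[MethylationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(path, lineno, f"expected 8 columns, got {len(fields)}")
            chrom, pos_s, _id, _ref, _alt, _qual, _filt, info = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(path, lineno, f"POS not an integer: {pos_s!r}")
            kv = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
            missing = {"CS", "CC", "NM", "NU"} - kv.keys()
            if missing:
                raise ParseError(path, lineno, f"INFO lacks {sorted(missing)}")
            try:
                n_meth, n_unmeth = int(kv["NM"]), int(kv["NU"])
            except ValueError:
                raise ParseError(path, lineno, "NM/NU not integers")
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(path, lineno, "negative count")
            try:
                records.append(
                    MethylationRecord(chrom, pos, kv["CS"], kv["CC"], n_meth, n_unmeth)
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
    records.sort(key=MethylationRecord.sort_key)
    return records


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(entries, path) -> None:
    """Write per-position values as bedGraph lines ``chrom start end value``.

    ``entries`` is an iterable of MethylationRecord (value = rate, skipping
    coverage-0 records is the caller's job) or of ``(chrom, pos_1based,
    value)`` tuples.  Output must be genome-sorted; unsorted input raises.
    """
    prev = None
    with open(path, "w") as fh:
        for entry in entries:
            if isinstance(entry, MethylationRecord):
                chrom, pos, value = entry.chrom, entry.pos, entry.rate
            else:
                chrom, pos, value = entry
            if not np.isfinite(value):
                raise ValueError(f"undefined value at {chrom}:{pos}")
            key = (chrom, pos)
            if prev is not None and prev[0] == chrom and key <= prev:
                raise ValueError(
                    f"input not sorted at {chrom}:{pos} (previous {prev[0]}:{prev[1]})"
                )
            prev = key
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{value:.6f}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, "expected 4 columns")
            out.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return out


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[AnnotationItem]:
    """Read BED 3/4/6 into AnnotationItems (0-based half-open).

    Lines with fewer than 4 columns get auto-generated names ``region_<i>``
    (1-based over data lines).
    """
    items: list[AnnotationItem] = []
    names_seen: set[str] = set()
    i = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >= 3 columns")
            i += 1
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "start/end not integers")
            if start >= end:
                raise ParseError(path, lineno, f"start {start} >= end {end}")
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else f"region_{i}"
            if name in names_seen:
                raise ParseError(path, lineno, f"duplicate region name {name!r}")
            names_seen.add(name)
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else None
            items.append(AnnotationItem(chrom, start, end, name, strand))
    return items


def write_bed(items: Iterable[AnnotationItem], path, scores=None) -> None:
    with open(path, "w") as fh:
        for i, item in enumerate(items):
            score = 0.0 if scores is None else scores[i]
            strand = item.strand or "+"
            fh.write(
                f"{item.chrom}\t{item.start}\t{item.end}\t{item.name}\t{score:g}\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# expression / pair tables


def read_expression_table(path) -> pd.DataFrame:
    """Gene x sample expression table from TSV (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    if (df.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_pairs_table(path) -> list[tuple[str, str]]:
    """DMR-gene association table: two tab-separated columns (dmr_id, gene_id)."""
    pairs = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#") or row[0] == "dmr_id":
                continue
            if len(row) < 2:
                raise ParseError(path, lineno, "expected 2 columns (dmr_id, gene_id)")
            pairs.append((row[0], row[1]))
    return pairs


def write_pairs_table(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("dmr_id\tgene_id\n")
        for dmr_id, gene_id in pairs:
            fh.write(f"{dmr_id}\t{gene_id}\n")


def write_dmr_bed(dmrs: Iterable[DMR], path) -> None:
    """DMR BED: name = unique id, score = -log10(q), strand + hyper / - hypo."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = -np.log10(max(d.q, 1e-300))
            strand = "+" if d.direction == "hyper" else "-"
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.name}\t{score:.4f}\t{strand}\n")


def write_dmr_table(dmrs: Iterable[DMR], path) -> None:
    cols = [
        "chrom", "start", "end", "name", "n_cpg", "mean_g1", "mean_g2",
        "mean_diff", "p_mwu", "p_ks2d", "q", "direction",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in dmrs:
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.name}\t{d.n_cpg}\t"
                f"{d.mean_g1:.6f}\t{d.mean_g2:.6f}\t{d.mean_diff:.6f}\t"
                f"{d.p_mwu:.6g}\t{d.p_ks2d:.6g}\t{d.q:.6g}\t{d.direction}\n"
            )


def read_dmr_table(path) -> list[DMR]:
    dmrs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            dmrs.append(
                DMR(
                    chrom=f[idx["chrom"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    n_cpg=int(f[idx["n_cpg"]]),
                    mean_g1=float(f[idx["mean_g1"]]),
                    mean_g2=float(f[idx["mean_g2"]]),
                    p_mwu=float(f[idx["p_mwu"]]),
                    p_ks2d=float(f[idx["p_ks2d"]]),
                    q=float(f[idx["q"]]),
                    name=f[idx["name"]],
                )
            )
    return dmrs
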