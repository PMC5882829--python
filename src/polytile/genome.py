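"""Reference genome data model and standard-format I/O.

All coordinates are kept 0-based, half-open internally; conversion to and
from 1-based inclusive happens only at the GFF3 boundary.  The reference
gene order (index 0..n-1 along the region) is the backbone every downstream
synteny operation works against.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import gffutils

__all__ = [
    "FormatError",
    "SequenceRecord",
    "CoordinateInterval",
    "GeneModel",
    "GenomicRegion",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_bed",
    "extract_qtl_region",
    "gene_density",
    "gc_percent",
]


class FormatError(ValueError):
    """Raised when an input stream violates its declared format."""


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CoordinateInterval:
    """0-based half-open genomic interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "CoordinateInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "CoordinateInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass
class GeneModel:
    """A reference gene: the unit of synteny.

    ``exons`` are non-overlapping, sorted by start and contained in
    ``interval``; ``cds_sequence`` is the exon concatenation (spliced).
    """

    gene_id: str
    interval: CoordinateInterval
    exons: list[CoordinateInterval] = field(default_factory=list)
    cds_sequence: str = ""

    def validate(self) -> None:
        prev_end = -1
        for ex in self.exons:
            if ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            if not self.interval.contains(ex):
                raise ValueError(f"{self.gene_id}: exon outside gene interval")
            prev_end = ex.end
        if self.cds_sequence and len(self.cds_sequence) != sum(len(e) for e in self.exons):
            raise ValueError(f"{self.gene_id}: cds length != sum of exon lengths")


@dataclass
class GenomicRegion:
    """A slice of a chromosome with its ordered gene complement."""

    interval: CoordinateInterval
    genes: list[GeneModel]
    sequence: str

    def __post_init__(self) -> None:
        starts = [g.interval.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError("genes not sorted by start")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(stream: TextIO | str) -> list[SequenceRecord]:
    """Parse FASTA into records; bodies concatenated, case upper-normalized.

    Raises :class:`FormatError` naming the line number if content precedes
    the first header.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        ident, _, desc = header.partition(" ")
        records.append(SequenceRecord(ident, "".join(chunks).upper(), desc))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise FormatError(f"line {lineno}: sequence data before first '>' header")
            chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], stream: TextIO, width: int = 70) -> None:
    for rec in records:
        head = f">{rec.id} {rec.description}".rstrip()
        stream.write(head + "\n")
        seq = rec.sequence
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(stream: TextIO | str, fasta: dict[str, str] | None = None) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon features into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates become 0-based half-open.  Only the
    primary (first-listed) transcript of each gene contributes exons.  When
    ``fasta`` (chrom -> sequence) is given, spliced CDS sequences are filled
    in from the exon intervals.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if not text.strip():
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"line {lineno}: expected 9 tab-separated columns")
        if int(cols[4]) < int(cols[3]):
            raise FormatError(f"line {lineno}: end < start")
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    gene_ids = set()
    for g in db.features_of_type("gene", order_by="start"):
        gene_ids.add(g.id)
        interval = CoordinateInterval(g.seqid, g.start - 1, g.end, g.strand if g.strand in "+-" else "+")
        transcripts = list(db.children(g, featuretype="mRNA", order_by="start"))
        exon_parent = transcripts[0] if transcripts else g
        exons = [
            CoordinateInterval(e.seqid, e.start - 1, e.end, interval.strand)
            for e in db.children(exon_parent, featuretype="exon", order_by="start")
        ]
        cds = ""
        if fasta is not None:
            chrom_seq = fasta[interval.chrom]
            cds = "".join(chrom_seq[e.start : e.end] for e in exons)
        model = GeneModel(g.id, interval, exons, cds)
        model.validate()
        genes.append(model)
    # orphan exon check: every exon's ancestry must reach a gene feature
    for e in db.features_of_type("exon"):
        parents = list(db.parents(e))
        if parents and not any(p.featuretype == "gene" for p in parents) and not gene_ids & {
            pid for p in parents for pid in [p.id]
        }:
            raise FormatError(f"exon {e.id}: Parent does not resolve to any gene")
    return genes


def write_gff3(genes: Sequence[GeneModel], stream: TextIO, source: str = "polytile") -> None:
    stream.write("##gff-version 3\n")
    for g in genes:
        iv = g.interval
        stream.write(
            f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.gene_id}\n"
        )
        mrna = f"{g.gene_id}.1"
        stream.write(
            f"{iv.chrom}\t{source}\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
        )
        for k, e in enumerate(g.exons, start=1):
            stream.write(
                f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{iv.strand}\t.\t"
                f"ID={mrna}.exon{k};Parent={mrna}\n"
            )


def write_bed(intervals: Iterable[tuple[CoordinateInterval, str]], stream: TextIO) -> None:
    """Write (interval, name) pairs as BED (0-based half-open, native)."""
    for iv, name in intervals:
        stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Region extraction and summaries


def extract_qtl_region(
    genes: Sequence[GeneModel], genome: Sequence[SequenceRecord], target: CoordinateInterval
) -> GenomicRegion:
    """Slice a target interval out of a chromosome with its overlapping genes.

    Membership is any overlap (>= 1 bp), not containment, so genes straddling
    the target boundaries are kept.
    """
    by_id = {rec.id: rec for rec in genome}
    if target.chrom not in by_id:
        raise KeyError(f"chromosome {target.chrom!r} not in genome")
    chrom_seq = by_id[target.chrom].sequence
    if target.end > len(chrom_seq):
        raise IndexError(
            f"target [{target.start}, {target.end}) exceeds chromosome length {len(chrom_seq)}"
        )
    hit = sorted(
        (g for g in genes if g.interval.overlaps(target)), key=lambda g: g.interval.start
    )
    return GenomicRegion(target, list(hit), chrom_seq[target.start : target.end])


def gene_density(total_bp: int, n_genes: int) -> float:
    """kb of sequence per gene, to one decimal (e.g. one gene per 23.6 kb)."""
    if n_genes < 1:
        raise ZeroDivisionError("gene density undefined for zero genes")
    return round((total_bp / 1000.0) / n_genes, 1)


def gc_percent(sequence: str) -> float:
    """GC percentage over A/C/G/T bases; N and other symbols are excluded."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return 0.0
    return 100.0 * gc / (gc + at)
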