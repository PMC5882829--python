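"""Synteny-based reconstruction of a polyploid region against a diploid
reference.

BAC contigs are mapped onto the reference gene order by aligning each
reference spliced CDS to the contig; runs of consecutively covered genes
form syntenic blocks; overlapping contigs are classified as coming from
the same or different homeologous chromosomes (complete sequence overlap
versus gene-only collinearity with unalignable intergenic DNA); and a
minimal tiling path of contigs is chosen per block by greedy interval
cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import networkx as nx

from .align import SubjectIndex, find_loci, revcomp
from .genome import CoordinateInterval, GenomicRegion
from .qc import Contig

__all__ = [
    "GeneHit",
    "BacAnnotation",
    "AnnotatedBac",
    "HomeologCall",
    "SyntenyBlock",
    "TilingPath",
    "annotate_bac",
    "map_to_reference",
    "classify_homeolog_pair",
    "group_homeologs",
    "detect_tandem_dups",
    "build_syntenic_blocks",
    "minimal_tiling_path",
    "region_report",
]


@dataclass
class GeneHit:
    reference_gene_index: int
    bac_interval: CoordinateInterval
    identity: float
    strand: str


@dataclass
class BacAnnotation:
    bac_id: str
    hits: list[GeneHit] = field(default_factory=list)  # sorted by bac position

    @property
    def gene_indices(self) -> set[int]:
        return {h.reference_gene_index for h in self.hits}

    @property
    def mapped_range(self) -> Optional[tuple[int, int]]:
        if not self.hits:
            return None
        idx = [h.reference_gene_index for h in self.hits]
        return min(idx), max(idx)

    @property
    def orientation(self) -> str:
        strands = {h.strand for h in self.hits}
        if strands == {"+"}:
            return "forward"
        if strands == {"-"}:
            return "reverse"
        return "mixed" if strands else "forward"


@dataclass
class AnnotatedBac:
    contig: Contig
    annotation: BacAnnotation

    @property
    def bac_id(self) -> str:
        return self.contig.id

    @property
    def length(self) -> int:
        return len(self.contig)


@dataclass
class HomeologCall:
    bac_a: str
    bac_b: str
    verdict: str  # same | different | unrelated
    overlap_identity: float = 0.0
    aligned_fraction: float = 0.0
    collinear: bool = False
    intergenic_aligned_fraction: Optional[float] = None
    low_confidence: bool = False


@dataclass
class SyntenyBlock:
    start_index: int  # first covered reference gene index (inclusive)
    end_index: int  # last covered reference gene index (inclusive)
    bac_ids: list[str] = field(default_factory=list)

    def gene_indices(self) -> range:
        return range(self.start_index, self.end_index + 1)


@dataclass
class TilingPath:
    block_paths: list[list[str]]  # minimal bac ids per block, in cover order
    total_bp: int

    @property
    def bac_ids(self) -> list[str]:
        return [b for block in self.block_paths for b in block]


# ---------------------------------------------------------------------------
# BAC annotation


def annotate_bac(
    bac: Contig,
    reference: GenomicRegion,
    min_identity: float = 0.8,
    min_cds_coverage: float = 0.5,
    max_intron_bp: int = 5_000,
) -> BacAnnotation:
    """Locate every reference gene on a BAC contig by exon-wise CDS alignment.

    Each exon of the spliced CDS is aligned to the contig separately (so
    introns on the contig cost nothing); exon hits are chained into gene
    loci by subject order, requiring exon indices to increase along the
    plus strand (decrease along the minus strand) with gaps below
    ``max_intron_bp`` — a repeat of an exon index starts a new locus, which
    is how adjacent tandem copies stay separate.  A locus is reported when
    the chained exons cover at least ``min_cds_coverage`` of the CDS at a
    length-weighted identity of at least ``min_identity``.  Where hits for
    different genes overlap on the BAC, the higher identity wins.
    """
    raw: list[GeneHit] = []
    subject = SubjectIndex(bac.sequence) if len(bac.sequence) > 10_000 else bac.sequence
    for gidx, gene in enumerate(reference.genes):
        if not gene.cds_sequence:
            continue
        exon_hits: dict[str, list[tuple[int, object]]] = {"+": [], "-": []}
        pos = 0
        for eidx, exon in enumerate(gene.exons):
            exon_seq = gene.cds_sequence[pos : pos + len(exon)]
            pos += len(exon)
            if len(exon_seq) < 40:
                continue
            for hit in find_loci(
                exon_seq,
                subject,
                min_identity=min_identity,
                min_query_cov=0.7,
                query_id=f"{gene.gene_id}.e{eidx}",
                subject_id=bac.id,
            ):
                exon_hits[hit.strand].append((eidx, hit))
        cds_len = len(gene.cds_sequence)
        for strand, ehits in exon_hits.items():
            ehits.sort(key=lambda t: t[1].subject_span.start)
            groups: list[list[tuple[int, object]]] = []
            for eidx, hit in ehits:
                extend = False
                if groups:
                    last_eidx, last_hit = groups[-1][-1]
                    order_ok = eidx > last_eidx if strand == "+" else eidx < last_eidx
                    gap = hit.subject_span.start - last_hit.subject_span.end
                    extend = order_ok and 0 <= gap <= max_intron_bp
                if extend:
                    groups[-1].append((eidx, hit))
                else:
                    groups.append([(eidx, hit)])
            for group in groups:
                aligned = sum(len(h.query_span) for _, h in group)
                coverage = min(aligned, cds_len) / cds_len
                if coverage < min_cds_coverage:
                    continue
                identity = sum(h.identity * len(h.query_span) for _, h in group) / aligned
                if identity < min_identity:
                    continue
                start = min(h.subject_span.start for _, h in group)
                end = max(h.subject_span.end for _, h in group)
                raw.append(GeneHit(gidx, CoordinateInterval(bac.id, start, end, strand), identity, strand))
    raw.sort(key=lambda h: (-h.identity, -len(h.bac_interval)))
    kept: list[GeneHit] = []
    for h in raw:
        clash = any(
            h.bac_interval.overlaps(k.bac_interval) and h.reference_gene_index != k.reference_gene_index
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: h.bac_interval.start)
    return BacAnnotation(bac.id, kept)


def map_to_reference(annotation: BacAnnotation) -> tuple[Optional[tuple[int, int]], bool]:
    """Mapped reference gene index range and whether the hit order along the
    BAC is collinear (strictly monotone after collapsing tandem copies)."""
    if not annotation.hits:
        return None, True
    seq = [h.reference_gene_index for h in annotation.hits]
    collapsed = [seq[0]]
    for x in seq[1:]:
        if x != collapsed[-1]:
            collapsed.append(x)
    if len(collapsed) <= 1:
        return annotation.mapped_range, True
    ascending = all(b > a for a, b in zip(collapsed, collapsed[1:]))
    descending = all(b < a for a, b in zip(collapsed, collapsed[1:]))
    return annotation.mapped_range, ascending or descending


# ---------------------------------------------------------------------------
# Homeolog discrimination


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(matches, mismatches, gap columns) from an extended cigar (=, X, I, D)."""
    m = x = g = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            if ch == "=":
                m += n
            elif ch == "X":
                x += n
            else:
                g += n
    return m, x, g


def _align_stats(a: str, b: str) -> tuple[float, float]:
    """(identity over aligned columns, aligned fraction of total columns)
    from a global edit-distance alignment."""
    if not a or not b:
        return 0.0, 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    m, x, g = _cigar_stats(res["cigar"])
    cols = m + x + g
    identity = m / (m + x) if (m + x) else 0.0
    return identity, (m + x) / cols if cols else 0.0


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def _shared_gene_layout(bac: AnnotatedBac, shared: set[int]) -> list[GeneHit]:
    """Hits on shared genes, in reference order (one best hit per gene)."""
    best: dict[int, GeneHit] = {}
    for h in bac.annotation.hits:
        g = h.reference_gene_index
        if g in shared and (g not in best or h.identity > best[g].identity):
            best[g] = h
    return [best[g] for g in sorted(best)]


def classify_homeolog_pair(
    a: AnnotatedBac,
    b: AnnotatedBac,
    same_identity: float = 0.99,
    same_aligned_frac: float = 0.95,
    intergenic_frac_cutoff: float = 0.5,
    min_identity: float = 0.8,
) -> HomeologCall:
    """Decide whether two overlapping BACs come from the same homeologous
    chromosome.

    Complete overlap of the shared span (high aligned fraction at near-
    perfect identity) indicates the same homeolog.  Total gene collinearity
    with well-aligning genes but unalignable intergenic DNA indicates
    different homeologs; anything else is called different with a
    low-confidence flag.  Disjoint mapped ranges are unrelated.
    """
    ra, rb = a.annotation.mapped_range, b.annotation.mapped_range
    if ra is None or rb is None or ra[1] < rb[0] or rb[1] < ra[0]:
        return HomeologCall(a.bac_id, b.bac_id, "unrelated")
    shared = a.annotation.gene_indices & b.annotation.gene_indices
    if not shared:
        return HomeologCall(a.bac_id, b.bac_id, "unrelated")

    hits_a = _shared_gene_layout(a, shared)
    hits_b = _shared_gene_layout(b, shared)
    strand_a = "-" if sum(h.strand == "-" for h in hits_a) > len(hits_a) / 2 else "+"
    strand_b = "-" if sum(h.strand == "-" for h in hits_b) > len(hits_b) / 2 else "+"
    span_a = a.contig.sequence[min(h.bac_interval.start for h in hits_a) : max(h.bac_interval.end for h in hits_a)]
    span_b = b.contig.sequence[min(h.bac_interval.start for h in hits_b) : max(h.bac_interval.end for h in hits_b)]
    identity, frac = _align_stats(_oriented(span_a, strand_a), _oriented(span_b, strand_b))
    if identity >= same_identity and frac >= same_aligned_frac:
        return HomeologCall(a.bac_id, b.bac_id, "same", identity, frac, collinear=True)

    # gene-level evidence
    _, coll_a = map_to_reference(BacAnnotation(a.bac_id, hits_a))
    _, coll_b = map_to_reference(BacAnnotation(b.bac_id, hits_b))
    collinear = coll_a and coll_b
    gene_ok = True
    for ha, hb in zip(hits_a, hits_b):
        ga = _oriented(a.contig.sequence[ha.bac_interval.start : ha.bac_interval.end], ha.strand)
        gb = _oriented(b.contig.sequence[hb.bac_interval.start : hb.bac_interval.end], hb.strand)
        g_ident, _ = _align_stats(ga, gb)
        if g_ident < min_identity:
            gene_ok = False
            break

    # intergenic evidence: the gaps between consecutive shared genes
    ig_cols = ig_aligned = 0
    ordered_a = sorted(hits_a, key=lambda h: h.bac_interval.start)
    ordered_b = sorted(hits_b, key=lambda h: h.bac_interval.start)
    if strand_a == "-":
        ordered_a = ordered_a[::-1]
    if strand_b == "-":
        ordered_b = ordered_b[::-1]
    by_gene_a = {h.reference_gene_index: h for h in ordered_a}
    by_gene_b = {h.reference_gene_index: h for h in ordered_b}
    genes_sorted = sorted(shared)
    for g1, g2 in zip(genes_sorted, genes_sorted[1:]):
        if g1 not in by_gene_a or g2 not in by_gene_a or g1 not in by_gene_b or g2 not in by_gene_b:
            continue
        gap_a = _gap_sequence(a.contig.sequence, by_gene_a[g1], by_gene_a[g2], strand_a)
        gap_b = _gap_sequence(b.contig.sequence, by_gene_b[g1], by_gene_b[g2], strand_b)
        if not gap_a or not gap_b:
            continue
        res = edlib.align(gap_a, gap_b, mode="NW", task="path")
        m, x, gcols = _cigar_stats(res["cigar"])
        ig_aligned += m + x
        ig_cols += m + x + gcols
    ig_frac = (ig_aligned / ig_cols) if ig_cols else frac

    if collinear and gene_ok and ig_frac < intergenic_frac_cutoff:
        return HomeologCall(a.bac_id, b.bac_id, "different", identity, frac, collinear, ig_frac)
    return HomeologCall(a.bac_id, b.bac_id, "different", identity, frac, collinear, ig_frac, low_confidence=True)


def _gap_sequence(seq: str, h1: GeneHit, h2: GeneHit, strand: str) -> str:
    lo = min(h1.bac_interval.end, h2.bac_interval.end)
    hi = max(h1.bac_interval.start, h2.bac_interval.start)
    if hi <= lo:
        return ""
    return _oriented(seq[lo:hi], strand)


def group_homeologs(calls: Sequence[HomeologCall]) -> tuple[list[set[str]], list[str]]:
    """Connected components of the 'same' relation, plus warnings for any
    'different' call landing inside a component ('same' wins)."""
    g = nx.Graph()
    for call in calls:
        g.add_node(call.bac_a)
        g.add_node(call.bac_b)
        if call.verdict == "same":
            g.add_edge(call.bac_a, call.bac_b)
    clusters = [set(c) for c in nx.connected_components(g)]
    membership = {node: i for i, cl in enumerate(clusters) for node in cl}
    warnings = []
    for call in calls:
        if call.verdict == "different" and membership.get(call.bac_a) == membership.get(call.bac_b):
            warnings.append(
                f"inconsistent calls: {call.bac_a} and {call.bac_b} are 'different' "
                "but connected through 'same' edges; keeping them together"
            )
    clusters.sort(key=lambda cl: sorted(cl)[0])
    return clusters, warnings


# ---------------------------------------------------------------------------
# Tandem duplications, blocks, tiling path


def detect_tandem_dups(annotation: BacAnnotation) -> list[int]:
    """Reference gene indices with two adjacent same-strand hits on the BAC
    (no other gene's hit in between)."""
    dups = []
    for h1, h2 in zip(annotation.hits, annotation.hits[1:]):
        if (
            h1.reference_gene_index == h2.reference_gene_index
            and h1.strand == h2.strand
            and h1.reference_gene_index not in dups
        ):
            dups.append(h1.reference_gene_index)
    return dups


def build_syntenic_blocks(
    annotations: Sequence[BacAnnotation],
    clusters: Sequence[set[str]] | None = None,
) -> tuple[list[SyntenyBlock], list[tuple[int, int]]]:
    """Maximal runs of consecutive reference gene indices covered by >= 1
    BAC, and the uncovered gaps strictly between them."""
    covered: set[int] = set()
    for ann in annotations:
        covered |= ann.gene_indices
    if not covered:
        return [], []
    blocks: list[SyntenyBlock] = []
    indices = sorted(covered)
    start = prev = indices[0]
    for x in indices[1:] + [None]:
        if x is not None and x == prev + 1:
            prev = x
            continue
        bac_ids = sorted(
            ann.bac_id
            for ann in annotations
            if any(start <= g <= prev for g in ann.gene_indices)
        )
        blocks.append(SyntenyBlock(start, prev, bac_ids))
        if x is not None:
            start = prev = x
    gaps = [
        (b1.end_index + 1, b2.start_index - 1)
        for b1, b2 in zip(blocks, blocks[1:])
    ]
    return blocks, gaps


def minimal_tiling_path(
    annotated: Sequence[AnnotatedBac],
) -> tuple[TilingPath, list[str]]:
    """Minimal BAC subset covering every covered reference gene, per block.

    Non-collinear BACs (possible chimeras) are excluded with a warning.
    Within each syntenic block the standard greedy interval cover applies:
    repeatedly take the BAC reaching furthest right among those covering
    the leftmost uncovered gene; ties break by longer sequence, then
    lexicographically smaller id.  Greedy is optimal for interval cover.
    """
    warnings = []
    usable: list[AnnotatedBac] = []
    for ab in annotated:
        if not ab.annotation.hits:
            continue
        _, collinear = map_to_reference(ab.annotation)
        if not collinear:
            warnings.append(f"{ab.bac_id}: non-collinear gene order, excluded from tiling path")
            continue
        usable.append(ab)
    blocks, _ = build_syntenic_blocks([ab.annotation for ab in usable])
    block_paths: list[list[str]] = []
    total_bp = 0
    for block in blocks:
        lo, hi = block.start_index, block.end_index
        intervals = []
        for ab in usable:
            r = ab.annotation.mapped_range
            if r and r[0] <= hi and r[1] >= lo:
                intervals.append((max(r[0], lo), min(r[1], hi), ab))
        path: list[str] = []
        current = lo
        while current <= hi:
            candidates = [(s, e, ab) for s, e, ab in intervals if s <= current <= e]
            best = max(candidates, key=lambda t: (t[1], t[2].length, _lex_min_key(t[2].bac_id)))
            path.append(best[2].bac_id)
            total_bp += best[2].length
            current = best[1] + 1
        block_paths.append(path)
    return TilingPath(block_paths, total_bp), warnings


def _lex_min_key(s: str):
    # smaller id must win under max()
    return tuple(-ord(c) for c in s)


def region_report(
    blocks: Sequence[SyntenyBlock],
    path: TilingPath,
    annotations: Sequence[BacAnnotation],
    tandem_dups: Sequence[int] | None = None,
    clusters: Sequence[set[str]] | None = None,
) -> dict:
    """All summary counts recomputed from the inputs."""
    covered: set[int] = set()
    for ann in annotations:
        covered |= ann.gene_indices
    return {
        "n_mapped_bacs": sum(1 for ann in annotations if ann.hits),
        "genes_covered": len(covered),
        "n_blocks": len(blocks),
        "n_gaps": max(len(blocks) - 1, 0),
        "n_tiling_bacs": len(path.bac_ids),
        "tiling_total_bp": path.total_bp,
        "n_tandem_dup_genes": len(set(tandem_dups or [])),
        "n_homeolog_clusters": len(clusters) if clusters is not None else None,
    }
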