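"""Gene-to-transcript matching and PCR marker design.

Reference genes are matched to target-genome transcripts by local
alignment; for each matched gene a single conserved exon is chosen and a
primer pair is designed inside it, so that the resulting amplicon spans no
intron and amplifies every homeologous copy of the gene.  One marker per
gene at most.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .align import AlignmentHit, Scoring, local_align, revcomp
from .genome import GeneModel, SequenceRecord

__all__ = [
    "MarkerPair",
    "best_hit",
    "conserved_single_exon_candidates",
    "primer_tm",
    "primer_gc",
    "design_primers",
    "design_marker_for_gene",
    "design_markers",
    "validate_marker_pair",
]

PRIMER_MIN_LEN = 18
PRIMER_MAX_LEN = 24
GC_MIN, GC_MAX = 40.0, 60.0
TM_MAX_DIFF = 3.0
AMPLICON_MIN, AMPLICON_MAX = 100, 1_000


@dataclass
class MarkerPair:
    marker_id: str
    gene_id: str
    forward: str
    reverse: str
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    expected_amplicon_bp: int


def primer_gc(primer: str) -> float:
    gc = sum(1 for b in primer if b in "GCgc")
    return 100.0 * gc / len(primer)


def primer_tm(primer: str) -> float:
    """Wallace-style GC-fraction melting temperature:
    Tm = 81.5 + 0.41 * GC% - 675 / length."""
    return 81.5 + 0.41 * primer_gc(primer) - 675.0 / len(primer)


def validate_marker_pair(pair: MarkerPair) -> list[str]:
    """Independent re-check of every marker-pair constraint; returns the
    list of violations (empty when valid)."""
    problems = []
    for name, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
        if not PRIMER_MIN_LEN <= len(primer) <= PRIMER_MAX_LEN:
            problems.append(f"{name} primer length {len(primer)} outside [{PRIMER_MIN_LEN}, {PRIMER_MAX_LEN}]")
        gc = primer_gc(primer)
        if not GC_MIN <= gc <= GC_MAX:
            problems.append(f"{name} GC {gc:.1f} outside [{GC_MIN}, {GC_MAX}]")
    if abs(primer_tm(pair.forward) - primer_tm(pair.reverse)) > TM_MAX_DIFF:
        problems.append("Tm difference exceeds limit")
    if not AMPLICON_MIN <= pair.expected_amplicon_bp <= AMPLICON_MAX:
        problems.append(f"amplicon {pair.expected_amplicon_bp} outside [{AMPLICON_MIN}, {AMPLICON_MAX}]")
    return problems


# ---------------------------------------------------------------------------
# Gene/transcript matching


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def best_hit(
    gene: GeneModel,
    transcripts: Sequence[SequenceRecord],
    e_cutoff: float = 1e-10,
    scoring: Scoring = Scoring(),
    prescreen_k: int | None = 11,
    prescreen_min_seeds: int = 3,
) -> Optional[AlignmentHit]:
    """Highest-scoring transcript hit for the gene's spliced CDS.

    Ties break by higher identity, then lexicographically smallest
    transcript id, making the result invariant to transcript order.
    Transcripts sharing fewer than ``prescreen_min_seeds`` exact
    ``prescreen_k``-mers with the CDS are skipped without alignment: any
    hit able to pass a meaningful e-value cutoff shares many exact seeds.
    Set ``prescreen_k=None`` to align against every transcript.
    """
    query_kmers = _kmer_set(gene.cds_sequence, prescreen_k) if prescreen_k else None
    best: Optional[AlignmentHit] = None
    for tx in transcripts:
        if not tx.sequence:
            continue
        if query_kmers is not None and len(tx.sequence) >= prescreen_k:
            shared = sum(1 for km in _kmer_set(tx.sequence, prescreen_k) if km in query_kmers)
            if shared < prescreen_min_seeds:
                continue
        hit = local_align(gene.cds_sequence, tx.sequence, scoring, query_id=gene.gene_id, subject_id=tx.id)
        if hit is None or hit.e_like >= e_cutoff:
            continue
        if best is None or (hit.score, hit.identity, _neg_id(hit)) > (best.score, best.identity, _neg_id(best)):
            best = hit
    return best


def _neg_id(hit: AlignmentHit):
    # lexicographically smaller subject_id must win ties -> invert for max()
    return tuple(-ord(c) for c in hit.subject_id)


def exon_cds_ranges(gene: GeneModel) -> list[tuple[int, int]]:
    """Each exon's coordinate range on the spliced CDS."""
    ranges = []
    pos = 0
    for ex in gene.exons:
        ranges.append((pos, pos + len(ex)))
        pos += len(ex)
    return ranges


def conserved_single_exon_candidates(
    gene: GeneModel,
    hit: AlignmentHit,
    min_identity: float = 0.95,
    min_len_bp: int = 140,
) -> list[int]:
    """Exon indices usable as single-exon marker templates.

    An exon qualifies when it lies fully inside the aligned CDS span, is at
    least ``min_len_bp`` long and its per-exon alignment identity is at
    least ``min_identity``.  Sorted by descending per-exon identity.
    """
    out: list[tuple[float, int]] = []
    for idx, (cs, ce) in enumerate(exon_cds_ranges(gene)):
        if ce - cs < min_len_bp:
            continue
        if cs < hit.query_span.start or ce > hit.query_span.end:
            continue
        ident, cols = hit.identity_in_query_range(cs, ce)
        if cols == 0 or ident < min_identity:
            continue
        out.append((ident, idx))
    out.sort(key=lambda t: (-t[0], t[1]))
    return [idx for _, idx in out]


def _query_to_subject(hit: AlignmentHit, q_start: int, q_end: int) -> tuple[int, int]:
    """Map a query coordinate range onto subject coordinates along the
    alignment path."""
    from .align import OP_MATCH, OP_MISMATCH, OP_INS

    qpos, spos = hit.query_span.start, hit.subject_span.start
    s_start = s_end = None
    for op in hit.ops:
        if qpos >= q_start and s_start is None:
            s_start = spos
        if op in (OP_MATCH, OP_MISMATCH):
            qpos += 1
            spos += 1
        elif op == OP_INS:
            spos += 1
        else:
            qpos += 1
        if qpos >= q_end:
            s_end = spos
            break
    if s_start is None:
        s_start = spos
    if s_end is None:
        s_end = spos
    return s_start, s_end


# ---------------------------------------------------------------------------
# Primer design


def _count_occurrences(primer: str, db: Sequence[SequenceRecord]) -> int:
    rc = revcomp(primer)
    total = 0
    for rec in db:
        total += rec.sequence.count(primer)
        total += rec.sequence.count(rc)
    return total


def design_primers(
    template: str,
    uniqueness_db: Sequence[SequenceRecord],
    min_amplicon: int = AMPLICON_MIN,
    max_amplicon: int = AMPLICON_MAX,
) -> Optional[tuple[str, str, int]]:
    """First primer pair meeting all constraints, scanning 18-24-mer windows
    from both template ends inward.

    Both primers must occur exactly once across ``uniqueness_db`` (counting
    both strands).  Returns (forward, reverse, amplicon length) or None.
    """
    n = len(template)
    if n < min_amplicon or n < 2 * PRIMER_MIN_LEN:
        return None
    for f_start in range(0, n - 2 * PRIMER_MIN_LEN + 1):
        for lf in range(PRIMER_MIN_LEN, PRIMER_MAX_LEN + 1):
            if f_start + lf > n:
                break
            fwd = template[f_start : f_start + lf]
            if not GC_MIN <= primer_gc(fwd) <= GC_MAX:
                continue
            if _count_occurrences(fwd, uniqueness_db) != 1:
                continue
            for r_end in range(n, f_start + min_amplicon - 1, -1):
                amplicon = r_end - f_start
                if amplicon < min_amplicon:
                    break
                if amplicon > max_amplicon:
                    continue
                for lr in range(PRIMER_MIN_LEN, PRIMER_MAX_LEN + 1):
                    if r_end - lr < f_start + lf:
                        break  # primers must not overlap
                    rev = revcomp(template[r_end - lr : r_end])
                    if not GC_MIN <= primer_gc(rev) <= GC_MAX:
                        continue
                    if abs(primer_tm(fwd) - primer_tm(rev)) > TM_MAX_DIFF:
                        continue
                    if _count_occurrences(rev, uniqueness_db) != 1:
                        continue
                    return fwd, rev, amplicon
    return None


def design_marker_for_gene(
    gene: GeneModel,
    transcripts: Sequence[SequenceRecord],
    e_cutoff: float = 1e-10,
    min_exon_identity: float = 0.95,
    min_exon_len: int = 140,
) -> Optional[MarkerPair]:
    """Full per-gene marker design: best transcript hit, conserved single
    exon, primer pair on the transcript template."""
    hit = best_hit(gene, transcripts, e_cutoff=e_cutoff)
    if hit is None:
        return None
    tx = next(t for t in transcripts if t.id == hit.subject_id)
    for exon_idx in conserved_single_exon_candidates(gene, hit, min_exon_identity, min_exon_len):
        cs, ce = exon_cds_ranges(gene)[exon_idx]
        ss, se = _query_to_subject(hit, cs, ce)
        template = tx.sequence[ss:se]
        design = design_primers(template, transcripts)
        if design is None:
            continue
        fwd, rev, amplicon = design
        return MarkerPair(
            marker_id=f"mk_{gene.gene_id}",
            gene_id=gene.gene_id,
            forward=fwd,
            reverse=rev,
            tm_f=round(primer_tm(fwd), 2),
            tm_r=round(primer_tm(rev), 2),
            gc_f=round(primer_gc(fwd), 2),
            gc_r=round(primer_gc(rev), 2),
            expected_amplicon_bp=amplicon,
        )
    return None


def design_markers(
    genes: Sequence[GeneModel],
    transcripts: Sequence[SequenceRecord],
    e_cutoff: float = 1e-10,
) -> list[MarkerPair]:
    """One marker per gene where a conserved single exon allows it."""
    markers = []
    for gene in genes:
        pair = design_marker_for_gene(gene, transcripts, e_cutoff=e_cutoff)
        if pair is not None:
            markers.append(pair)
    return markers
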