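"""Synthetic polyploid genome region, BAC library, and pool-level contigs.

The simulator emulates the situation where a complex polyploid genome
(sugarcane-like: 8-12 homeologous copies, ~51% repetitive intergenic DNA,
tandem gene duplications) must be reconstructed against a diploid relative
(sorghum-like reference region of ~61 genes in ~687 kb).  Every random
choice is recorded as ground truth, so downstream screening, QC and synteny
stages can be validated exactly.

Sequencing and assembly are not modeled read-by-read: each sequencing pool
yields one error-free contig per clone insert plus short/low-coverage decoy
contigs, which reproduces the statistical shape of a pool assembly without
reimplementing an assembler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genome import CoordinateInterval, GeneModel, GenomicRegion, SequenceRecord
from .qc import Contig

__all__ = [
    "SimulationParams",
    "GeneCopyTruth",
    "TeInsertion",
    "HomeologTruth",
    "BacClone",
    "BacLibrary",
    "simulate_reference_region",
    "derive_homeologs",
    "simulate_transcriptome",
    "simulate_bac_library",
    "simulate_pool_contigs",
    "default_vector",
    "default_host",
]

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def _to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _to_seq(rng.integers(0, 4, size=length, dtype=np.uint8))


def _mutate_subs(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases at the given per-base rate (always to a different base)."""
    if rate <= 0 or len(codes) == 0:
        return codes
    mask = rng.random(len(codes)) < rate
    k = int(mask.sum())
    if k:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    return codes


def _mutate_indels(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Geometric-length (mean 3 bp) insertions/deletions at the given rate."""
    if rate <= 0 or len(codes) == 0:
        return codes
    positions = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(positions) == 0:
        return codes
    pieces: list[np.ndarray] = []
    prev = 0
    for pos in positions:
        size = int(rng.geometric(1.0 / 3.0))
        if rng.random() < 0.5:  # insertion
            pieces.append(codes[prev:pos])
            pieces.append(rng.integers(0, 4, size=size, dtype=np.uint8))
            prev = pos
        else:  # deletion
            pieces.append(codes[prev:pos])
            prev = min(pos + size, len(codes))
    pieces.append(codes[prev:])
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class SimulationParams:
    """Study conditions for the synthetic polyploid region.

    Defaults emulate the sugarcane/sorghum setting: 61 genes in 687 kb,
    ~10 homeologous copies diverged ~2% in genes and ~10% between genes,
    51% of each homeolog covered by transposable elements (LTR:DNA:non-LTR
    counts near 41:8:2, Gypsy:Copia 58:42, element lengths 146-11,800 bp),
    six tandemly duplicated genes, 53 of 61 genes detectable in the
    transcriptome, and 8.25% host (E. coli-like) read contamination.
    """

    n_genes: int = 61
    region_length_bp: int = 687_000
    ploidy: int = 10
    genic_divergence: float = 0.02
    intergenic_divergence: float = 0.10
    repeat_fraction_target: float = 0.51
    te_class_mix: tuple[float, float, float] = (41.0, 8.0, 2.0)  # LTR : DNA : non-LTR
    ltr_family_mix: tuple[float, float] = (58.0, 42.0)  # Gypsy : Copia
    te_length_range: tuple[int, int] = (146, 11_800)
    n_tandem_dup_genes: int = 6
    transcript_detect_count: int = 53
    gene_loss_rate: float = 0.02
    host_read_fraction: float = 0.0825
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.ploidy < 2:
            raise ValueError("ploidy must be >= 2")
        for name in ("genic_divergence", "intergenic_divergence", "gene_loss_rate", "host_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.repeat_fraction_target <= 0.9:
            raise ValueError("repeat_fraction_target must be in [0, 0.9]")
        if self.n_tandem_dup_genes > self.n_genes:
            raise ValueError("n_tandem_dup_genes cannot exceed n_genes")
        if self.transcript_detect_count > self.n_genes:
            raise ValueError("transcript_detect_count cannot exceed n_genes")
        if sum(self.te_class_mix) <= 0:
            raise ValueError("te_class_mix must have positive mass")

    @property
    def te_class_probs(self) -> np.ndarray:
        p = np.asarray(self.te_class_mix, dtype=float)
        return p / p.sum()

    @property
    def ltr_family_probs(self) -> np.ndarray:
        p = np.asarray(self.ltr_family_mix, dtype=float)
        return p / p.sum()


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass
class GeneCopyTruth:
    ref_index: int
    present: bool
    interval: Optional[CoordinateInterval] = None  # on the homeolog
    tandem_dup: bool = False
    dup_interval: Optional[CoordinateInterval] = None


@dataclass
class TeInsertion:
    te_class: str  # LTR / DNA / nonLTR
    family: str
    interval: CoordinateInterval


@dataclass
class HomeologTruth:
    homeolog_id: int
    genes: list[GeneCopyTruth] = field(default_factory=list)
    te_insertions: list[TeInsertion] = field(default_factory=list)
    length: int = 0

    def repeat_fraction(self) -> float:
        if self.length == 0:
            return 0.0
        return sum(len(t.interval) for t in self.te_insertions) / self.length

    def surviving_order(self) -> list[int]:
        return [g.ref_index for g in self.genes if g.present]


@dataclass
class BacClone:
    """A simulated clone with a 3D address and a ground-truth source."""

    clone_id: str
    address: tuple[int, int, int]  # (plate, row, column)
    source_homeolog: int
    source_interval: CoordinateInterval
    insert_sequence: str


@dataclass
class BacLibrary:
    clones: list[BacClone]
    layout: tuple[int, int, int]  # (n_plates, n_rows, n_cols)

    def __len__(self) -> int:
        return len(self.clones)

    def by_address(self) -> dict[tuple[int, int, int], BacClone]:
        return {c.address: c for c in self.clones}


# ---------------------------------------------------------------------------
# Reference region


def simulate_reference_region(params: SimulationParams, seed: int | None = None) -> GenomicRegion:
    """Random reference region: non-overlapping multi-exon genes separated by
    random intergenic spacers.  Deterministic for a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_genes
    structures = []
    for _ in range(n):
        n_exons = int(rng.integers(1, 6))
        exon_lens = rng.integers(150, 601, size=n_exons)
        intron_lens = rng.integers(80, 401, size=max(n_exons - 1, 0))
        structures.append((exon_lens, intron_lens))
    gene_lens = [int(e.sum() + i.sum()) for e, i in structures]
    min_spacer = 100
    slack = params.region_length_bp - sum(gene_lens) - (n + 1) * min_spacer
    if slack < 0:
        raise ValueError(
            f"region of {params.region_length_bp} bp too small for {n} genes "
            f"(need >= {sum(gene_lens) + (n + 1) * min_spacer} bp)"
        )
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    spacers = extra + min_spacer
    sequence = _random_seq(rng, params.region_length_bp)
    genes: list[GeneModel] = []
    pos = 0
    chrom = "ref"
    for idx in range(n):
        pos += int(spacers[idx])
        start = pos
        exons = []
        exon_lens, intron_lens = structures[idx]
        for k, el in enumerate(exon_lens):
            exons.append(CoordinateInterval(chrom, pos, pos + int(el)))
            pos += int(el)
            if k < len(intron_lens):
                pos += int(intron_lens[k])
        interval = CoordinateInterval(chrom, start, pos)
        cds = "".join(sequence[e.start : e.end] for e in exons)
        genes.append(GeneModel(f"g{idx:03d}", interval, exons, cds))
    region = GenomicRegion(CoordinateInterval(chrom, 0, params.region_length_bp), genes, sequence)
    for g in genes:
        g.validate()
    return region


# ---------------------------------------------------------------------------
# Transposable-element library


@dataclass(frozen=True)
class _TeFamily:
    name: str
    te_class: str
    length: int


_TE_FAMILIES = {
    "LTR": {
        "Gypsy": [_TeFamily("Gypsy-1", "LTR", 11_800), _TeFamily("Gypsy-2", "LTR", 9_400), _TeFamily("Gypsy-3", "LTR", 8_000)],
        "Copia": [_TeFamily("Copia-1", "LTR", 7_000), _TeFamily("Copia-2", "LTR", 4_800)],
    },
    "DNA": [_TeFamily("Stowaway", "DNA", 146), _TeFamily("DNA-hAT", "DNA", 900), _TeFamily("DNA-CACTA", "DNA", 2_400)],
    "nonLTR": [_TeFamily("LINE-1", "nonLTR", 3_200), _TeFamily("LINE-2", "nonLTR", 5_100)],
}


def _build_te_library(rng: np.random.Generator) -> dict[str, str]:
    """Synthetic TE consensus sequences, one per family.  LTR elements carry
    a literal 300-bp terminal repeat."""
    lib: dict[str, str] = {}
    families = [f for fams in _TE_FAMILIES["LTR"].values() for f in fams]
    families += _TE_FAMILIES["DNA"] + _TE_FAMILIES["nonLTR"]
    for fam in families:
        seq = _random_seq(rng, fam.length)
        if fam.te_class == "LTR" and fam.length > 700:
            seq = seq[:300] + seq[300 : fam.length - 300] + seq[:300]
        lib[fam.name] = seq
    return lib


def _sample_te_copies(
    params: SimulationParams, te_lib: dict[str, str], needed_bp: int, rng: np.random.Generator
) -> list[tuple[_TeFamily, str]]:
    """TE copies (class chosen by te_class_mix, Gypsy/Copia by ltr_family_mix)
    until their summed length reaches needed_bp."""
    classes = ["LTR", "DNA", "nonLTR"]
    copies: list[tuple[_TeFamily, str]] = []
    total = 0
    while total < needed_bp:
        cls = classes[int(rng.choice(3, p=params.te_class_probs))]
        if cls == "LTR":
            group = "Gypsy" if rng.random() < params.ltr_family_probs[0] else "Copia"
            fam = _TE_FAMILIES["LTR"][group][int(rng.integers(0, len(_TE_FAMILIES["LTR"][group])))]
        else:
            fams = _TE_FAMILIES[cls]
            fam = fams[int(rng.integers(0, len(fams)))]
        codes = _mutate_subs(_to_codes(te_lib[fam.name]), 0.03, rng)
        copies.append((fam, _to_seq(codes)))
        total += len(codes)
    return copies


# ---------------------------------------------------------------------------
# Homeologs


def derive_homeologs(
    reference: GenomicRegion, params: SimulationParams, seed: int | None = None
) -> tuple[list[SequenceRecord], list[HomeologTruth]]:
    """Derive H homeologous copies of the reference region.

    Genic positions are substituted at ``genic_divergence``; intergenic
    spacers at ``intergenic_divergence`` plus short indels (10% of the
    substitution rate, geometric mean 3 bp); synthetic TE copies fill the
    intergenic space up to ``repeat_fraction_target``; ``n_tandem_dup_genes``
    reference genes receive an adjacent duplicate on one random homeolog
    each.  All of it is recorded in :class:`HomeologTruth`.
    """
    params.validate()
    base_seed = params.seed if seed is None else seed
    master = np.random.default_rng([base_seed, 7_001])
    te_lib = _build_te_library(np.random.default_rng([base_seed, 7_002]))
    n = len(reference.genes)
    # pick tandem-duplicated genes and their carrier homeologs globally
    dup_genes = master.choice(n, size=params.n_tandem_dup_genes, replace=False) if params.n_tandem_dup_genes else np.empty(0, int)
    dup_homeolog = {int(g): int(master.integers(0, params.ploidy)) for g in dup_genes}

    # reference segmented into alternating intergenic / gene pieces
    boundaries = []
    pos = 0
    for g in reference.genes:
        boundaries.append(("intergenic", pos, g.interval.start))
        boundaries.append(("gene", g.interval.start, g.interval.end))
        pos = g.interval.end
    boundaries.append(("intergenic", pos, len(reference.sequence)))

    homeologs: list[SequenceRecord] = []
    truths: list[HomeologTruth] = []
    indel_rate = 0.1 * params.intergenic_divergence
    for h in range(params.ploidy):
        rng = np.random.default_rng([base_seed, 7_100 + h])
        lost = rng.random(n) < params.gene_loss_rate
        for gidx, carrier in dup_homeolog.items():
            if carrier == h:
                lost[gidx] = False  # a duplicated copy implies the gene survived here
        base_len = len(reference.sequence) - int(
            sum(len(reference.genes[i].interval) for i in range(n) if lost[i])
        )
        f = params.repeat_fraction_target
        needed = int(f / (1.0 - f) * base_len) if f > 0 else 0
        te_copies = _sample_te_copies(params, te_lib, needed, rng)
        n_intergenic = n + 1
        seg_lens = np.array([end - start for kind, start, end in boundaries if kind == "intergenic"], dtype=float)
        weights = seg_lens + 1.0
        weights /= weights.sum()
        te_segment = rng.choice(n_intergenic, size=len(te_copies), p=weights)

        pieces: list[str] = []
        truth = HomeologTruth(homeolog_id=h)
        out_pos = 0
        ig_index = 0
        gene_idx = 0
        for kind, start, end in boundaries:
            if kind == "intergenic":
                codes = _to_codes(reference.sequence[start:end])
                codes = _mutate_subs(codes, params.intergenic_divergence, rng)
                codes = _mutate_indels(codes, indel_rate, rng)
                seg = _to_seq(codes)
                copies_here = [te_copies[i] for i in np.nonzero(te_segment == ig_index)[0]]
                if copies_here:
                    cuts = np.sort(rng.integers(0, len(seg) + 1, size=len(copies_here)))
                    prev = 0
                    for (fam, te_seq), cut in zip(copies_here, cuts):
                        pieces.append(seg[prev:int(cut)])
                        out_pos += int(cut) - prev
                        truth.te_insertions.append(
                            TeInsertion(fam.te_class, fam.name, CoordinateInterval(f"h{h}", out_pos, out_pos + len(te_seq)))
                        )
                        pieces.append(te_seq)
                        out_pos += len(te_seq)
                        prev = int(cut)
                    pieces.append(seg[prev:])
                    out_pos += len(seg) - prev
                else:
                    pieces.append(seg)
                    out_pos += len(seg)
                ig_index += 1
            else:
                gidx = gene_idx
                gene_idx += 1
                if lost[gidx]:
                    truth.genes.append(GeneCopyTruth(gidx, present=False))
                    continue
                codes = _mutate_subs(_to_codes(reference.sequence[start:end]), params.genic_divergence, rng)
                seg = _to_seq(codes)
                iv = CoordinateInterval(f"h{h}", out_pos, out_pos + len(seg))
                pieces.append(seg)
                out_pos += len(seg)
                rec = GeneCopyTruth(gidx, present=True, interval=iv)
                if dup_homeolog.get(gidx) == h:
                    spacer = _random_seq(rng, int(rng.integers(20, 81)))
                    pieces.append(spacer)
                    out_pos += len(spacer)
                    dup_codes = _mutate_subs(_to_codes(reference.sequence[start:end]), params.genic_divergence, rng)
                    dup_seq = _to_seq(dup_codes)
                    rec.tandem_dup = True
                    rec.dup_interval = CoordinateInterval(f"h{h}", out_pos, out_pos + len(dup_seq))
                    pieces.append(dup_seq)
                    out_pos += len(dup_seq)
                truth.genes.append(rec)
        seq = "".join(pieces)
        truth.length = len(seq)
        homeologs.append(SequenceRecord(f"h{h}", seq, f"homeolog {h}"))
        truths.append(truth)
    return homeologs, truths


# ---------------------------------------------------------------------------
# Transcriptome


def simulate_transcriptome(
    reference: GenomicRegion,
    truth: Sequence[HomeologTruth] | None,
    params: SimulationParams,
    seed: int | None = None,
) -> list[SequenceRecord]:
    """Spliced transcripts for ``transcript_detect_count`` genes chosen
    uniformly at random; sequences carry genic-divergence noise relative to
    the reference (the transcriptome belongs to the polyploid target)."""
    params.validate()
    rng = np.random.default_rng([(params.seed if seed is None else seed), 7_200])
    n = len(reference.genes)
    if params.transcript_detect_count > n:
        raise ValueError("transcript_detect_count exceeds number of genes")
    detected = np.sort(rng.choice(n, size=params.transcript_detect_count, replace=False))
    out = []
    for gidx in detected:
        gene = reference.genes[int(gidx)]
        codes = _mutate_subs(_to_codes(gene.cds_sequence), params.genic_divergence, rng)
        out.append(SequenceRecord(f"tx_{gene.gene_id}", _to_seq(codes), f"transcript of {gene.gene_id}"))
    return out


# ---------------------------------------------------------------------------
# BAC library


def simulate_bac_library(
    homeologs: Sequence[SequenceRecord],
    n_clones: int,
    insert_mean_bp: int = 100_000,
    insert_sd_bp: int = 15_000,
    layout: tuple[int, int, int] = (5, 10, 10),
    seed: int = 0,
) -> BacLibrary:
    """Random clone library over the homeolog set.

    Each clone picks a homeolog uniformly, an insert length from a normal
    distribution truncated to [mean/2, 2*mean], and a start drawn uniformly
    over an insert-length-extended range and clamped into bounds.  The
    clamping emulates a library prepared from whole chromosomes rather than
    from the excised region: loci near the region edges stay covered at
    full depth instead of being starved of clones.  Addresses are assigned
    row-major over the (plates, rows, cols) layout.
    """
    n_plates, n_rows, n_cols = layout
    capacity = n_plates * n_rows * n_cols
    if n_clones > capacity:
        raise ValueError(f"{n_clones} clones exceed layout capacity {capacity}")
    rng = np.random.default_rng([seed, 7_300])
    lo, hi = insert_mean_bp // 2, 2 * insert_mean_bp
    clones: list[BacClone] = []
    for i in range(n_clones):
        h = int(rng.integers(0, len(homeologs)))
        seq = homeologs[h].sequence
        while True:
            length = int(round(rng.normal(insert_mean_bp, insert_sd_bp)))
            if lo <= length <= hi:
                break
        length = min(length, len(seq))
        raw = int(rng.integers(-(length - 1), len(seq)))
        start = min(max(raw, 0), len(seq) - length)
        address = (i // (n_rows * n_cols), (i % (n_rows * n_cols)) // n_cols, i % n_cols)
        clones.append(
            BacClone(
                clone_id=f"bac{i:04d}",
                address=address,
                source_homeolog=h,
                source_interval=CoordinateInterval(homeologs[h].id, start, start + length),
                insert_sequence=seq[start : start + length],
            )
        )
    return BacLibrary(clones, layout)


# ---------------------------------------------------------------------------
# Pool-level reads and contigs


def default_vector(length: int = 7_500) -> SequenceRecord:
    """Synthetic cloning-vector stand-in (fixed internal seed)."""
    return SequenceRecord("vector", _random_seq(np.random.default_rng(424_242), length), "synthetic BAC vector")


def default_host(length: int = 40_000) -> SequenceRecord:
    """Synthetic host-genome stand-in for E. coli contamination (fixed seed)."""
    return SequenceRecord("host", _random_seq(np.random.default_rng(515_151), length), "synthetic host genome")


def simulate_pool_contigs(
    sequencing_pool: Sequence[BacClone],
    error_rate: float = 0.01,
    host_read_fraction: float = 0.0825,
    vector: SequenceRecord | None = None,
    seed: int = 0,
    pool_id: str = "pool",
    reads_per_clone: int = 60,
    read_len_mean: int = 1_200,
    read_len_sd: int = 500,
    decoys_per_clone: float = 2.5,
    pool_mean_coverage: float = 60.0,
    host: SequenceRecord | None = None,
) -> tuple[list[SequenceRecord], list[Contig]]:
    """Reads and assembled-contig stand-ins for one sequencing pool.

    Reads are insert fragments with point errors, a fraction of host decoy
    reads (marked ``host`` in the description for truth joins), and vector
    fragments attached to a subset of read ends.  Contigs are one error-free
    copy per clone insert plus short/low-coverage decoys; defaults leave
    roughly 60% of contigs under 50 kb, as seen in real pool assemblies.
    """
    if not sequencing_pool:
        return [], []
    rng = np.random.default_rng([seed, 7_400])
    vector = vector if vector is not None else default_vector()
    host = host if host is not None else default_host()
    reads: list[SequenceRecord] = []
    ridx = 0
    for clone in sequencing_pool:
        ins = clone.insert_sequence
        for _ in range(reads_per_clone):
            length = max(200, int(rng.normal(read_len_mean, read_len_sd)))
            length = min(length, len(ins))
            start = int(rng.integers(0, len(ins) - length + 1))
            codes = _mutate_subs(_to_codes(ins[start : start + length]), error_rate, rng)
            seq = _to_seq(codes)
            if rng.random() < 0.3:  # vector carry-over on one end
                vlen = int(rng.integers(30, 301))
                vstart = int(rng.integers(0, len(vector.sequence) - vlen + 1))
                vfrag = vector.sequence[vstart : vstart + vlen]
                seq = vfrag + seq if rng.random() < 0.5 else seq + vfrag
            reads.append(SequenceRecord(f"{pool_id}_r{ridx:06d}", seq, f"clone={clone.clone_id}"))
            ridx += 1
    n_insert_reads = len(reads)
    f = host_read_fraction
    n_host = int(round(f / (1.0 - f) * n_insert_reads)) if f > 0 else 0
    for _ in range(n_host):
        length = max(200, int(rng.normal(read_len_mean, read_len_sd)))
        length = min(length, len(host.sequence))
        start = int(rng.integers(0, len(host.sequence) - length + 1))
        reads.append(SequenceRecord(f"{pool_id}_r{ridx:06d}", host.sequence[start : start + length], "host"))
        ridx += 1
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]

    contigs: list[Contig] = []
    cidx = 0
    for clone in sequencing_pool:
        cov = max(1.0, float(rng.normal(pool_mean_coverage, 0.15 * pool_mean_coverage)))
        contigs.append(Contig(f"{pool_id}_c{cidx:03d}", clone.insert_sequence, cov, pool_id))
        cidx += 1
    n_decoys = int(round(decoys_per_clone * len(sequencing_pool)))
    for _ in range(n_decoys):
        if rng.random() < 0.85:
            length = int(rng.integers(5_000, 49_000))
        else:
            length = int(rng.integers(50_000, 80_000))
        cov = float(rng.uniform(0.5, 0.15 * pool_mean_coverage))
        contigs.append(Contig(f"{pool_id}_c{cidx:03d}", _random_seq(rng, length), cov, pool_id))
        cidx += 1
    return reads, contigs
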