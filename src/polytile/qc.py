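"""Read trimming/decontamination and per-pool contig statistics.

The statistics mirror what a pooled-BAC sequencing project reports per
sequencing pool: trimmed read counts, host-contamination percentage,
contig count, extreme contig lengths, total assembly length, N50 and GC%,
plus a cross-pool aggregate row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome import SequenceRecord, gc_percent

__all__ = [
    "Contig",
    "PoolStats",
    "AggregateReport",
    "read_reads",
    "trim_and_decontaminate",
    "contig_stats",
    "n50",
    "filter_contigs",
    "aggregate_report",
    "stats_table",
]


def read_reads(path_or_stream) -> list[SequenceRecord]:
    """Read sequencing reads from FASTA or FASTQ (format sniffed from the
    first character; FASTQ qualities are ignored)."""
    import io

    from Bio import SeqIO

    from .genome import read_fasta

    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            text = fh.read()
    stripped = text.lstrip()
    if not stripped:
        return []
    if stripped[0] == "@":
        return [
            SequenceRecord(rec.id, str(rec.seq).upper(), rec.description)
            for rec in SeqIO.parse(io.StringIO(text), "fastq")
        ]
    return read_fasta(text)


@dataclass
class Contig:
    id: str
    sequence: str
    coverage: float = 0.0
    pool_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PoolStats:
    pool_id: str
    n_bacs: int
    trimmed_reads: int
    host_pct: float
    n_contigs: int
    longest: int
    smallest: int
    total_length: int
    n50: int
    gc_pct: float


@dataclass
class AggregateReport:
    n_pools: int
    total_bacs: int
    total_reads: int
    mean_reads: int
    total_contigs: int
    mean_contigs: int
    total_length: int
    max_longest: int
    mean_host_pct: float
    mean_gc_pct: float
    n_filtered: int | None = None
    pct_filtered: float | None = None


# ---------------------------------------------------------------------------
# Read screening


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def trim_and_decontaminate(
    reads: Sequence[SequenceRecord],
    vector: SequenceRecord | None,
    host: Sequence[SequenceRecord] | SequenceRecord | None,
    min_len: int = 500,
    host_k: int = 21,
    host_frac: float = 0.5,
    vector_seed: int = 20,
) -> tuple[list[SequenceRecord], float, dict[str, int]]:
    """Screen raw reads before correction/assembly.

    Host screening is k-mer based (k=21, both strands): a read is discarded
    as host when at least ``host_frac`` of its k-mers occur in the host
    genome.  Vector matches are located by exact >= ``vector_seed``-bp seeds
    extended to maximal runs: terminal matches are trimmed off, interior
    matches are masked with N.  Reads shorter than ``min_len`` after
    trimming are dropped.  Returns (kept reads, host percentage of input,
    per-category removal counts).
    """
    if not reads:
        return [], 0.0, {"host": 0, "short": 0, "input": 0}
    host_kmers: set[str] = set()
    if host is not None:
        host_list = [host] if isinstance(host, SequenceRecord) else list(host)
        for rec in host_list:
            host_kmers |= _kmers(rec.sequence, host_k)
            host_kmers |= _kmers(_revcomp(rec.sequence), host_k)
    vec_seeds: set[str] = set()
    if vector is not None:
        vec_seeds = _kmers(vector.sequence, vector_seed) | _kmers(_revcomp(vector.sequence), vector_seed)

    kept: list[SequenceRecord] = []
    n_host = n_short = 0
    for read in reads:
        seq = read.sequence
        if host_kmers and len(seq) >= host_k:
            total = len(seq) - host_k + 1
            n_hit = sum(1 for i in range(total) if seq[i : i + host_k] in host_kmers)
            if n_hit >= host_frac * total:
                n_host += 1
                continue
        if vec_seeds and len(seq) >= vector_seed:
            match = np.zeros(len(seq), dtype=bool)
            for i in range(len(seq) - vector_seed + 1):
                if seq[i : i + vector_seed] in vec_seeds:
                    match[i : i + vector_seed] = True
            if match.any():
                # trim terminal vector runs, mask interior ones
                start = 0
                while start < len(seq) and match[start]:
                    start += 1
                end = len(seq)
                while end > start and match[end - 1]:
                    end -= 1
                interior = match[start:end]
                chars = np.frombuffer(seq[start:end].encode(), dtype=np.uint8).copy()
                chars[interior] = ord("N")
                seq = chars.tobytes().decode()
        if len(seq) < min_len:
            n_short += 1
            continue
        kept.append(SequenceRecord(read.id, seq, read.description))
    host_pct = 100.0 * n_host / len(reads)
    return kept, host_pct, {"host": n_host, "short": n_short, "input": len(reads)}


# ---------------------------------------------------------------------------
# Contig statistics


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    if not lengths:
        return 0
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    return int(arr[np.nonzero(np.cumsum(arr) >= half)[0][0]])


def contig_stats(
    contigs: Sequence[Contig], n_bacs: int, trimmed_reads: int, host_pct: float, pool_id: str | None = None
) -> PoolStats:
    pid = pool_id if pool_id is not None else (contigs[0].pool_id if contigs else "")
    if not contigs:
        return PoolStats(pid, n_bacs, trimmed_reads, host_pct, 0, 0, 0, 0, 0, 0.0)
    lengths = [len(c) for c in contigs]
    all_seq = "".join(c.sequence for c in contigs)
    return PoolStats(
        pool_id=pid,
        n_bacs=n_bacs,
        trimmed_reads=trimmed_reads,
        host_pct=host_pct,
        n_contigs=len(contigs),
        longest=max(lengths),
        smallest=min(lengths),
        total_length=int(sum(lengths)),
        n50=n50(lengths),
        gc_pct=round(gc_percent(all_seq), 2),
    )


def filter_contigs(
    contigs: Sequence[Contig],
    min_len: int = 50_000,
    coverage_rule: float | Callable[[Contig, float], bool] | None = 0.25,
) -> tuple[list[Contig], list[Contig], float]:
    """Drop contigs shorter than ``min_len`` (strict) or with low coverage.

    "Low coverage" defaults to coverage < 0.25 x the median coverage of the
    contig's pool — scale-free and robust to per-pool depth.  Pass a float
    to change the fraction, a callable ``f(contig, pool_median) -> bool``
    (True = low), or None to disable the coverage rule.  Returns
    (kept, removed, percent removed to one decimal).
    """
    if not contigs:
        return [], [], 0.0
    medians: dict[str, float] = {}
    for pid in {c.pool_id for c in contigs}:
        covs = [c.coverage for c in contigs if c.pool_id == pid]
        medians[pid] = float(np.median(covs))
    kept, removed = [], []
    for c in contigs:
        low_cov = False
        if coverage_rule is not None:
            med = medians[c.pool_id]
            if callable(coverage_rule):
                low_cov = coverage_rule(c, med)
            else:
                low_cov = c.coverage < coverage_rule * med
        if len(c) < min_len or low_cov:
            removed.append(c)
        else:
            kept.append(c)
    pct = round(100.0 * len(removed) / len(contigs), 1)
    return kept, removed, pct


def aggregate_report(rows: Sequence[PoolStats]) -> AggregateReport:
    """Totals and means over per-pool rows.

    Count means are rounded to the nearest integer (matching how such
    tables print them); percentage means to two decimals.
    """
    if not rows:
        raise ValueError("aggregate_report requires at least one pool row")
    total_reads = sum(r.trimmed_reads for r in rows)
    total_contigs = sum(r.n_contigs for r in rows)
    return AggregateReport(
        n_pools=len(rows),
        total_bacs=sum(r.n_bacs for r in rows),
        total_reads=total_reads,
        mean_reads=int(round(total_reads / len(rows))),
        total_contigs=total_contigs,
        mean_contigs=int(round(total_contigs / len(rows))),
        total_length=sum(r.total_length for r in rows),
        max_longest=max(r.longest for r in rows),
        mean_host_pct=round(sum(r.host_pct for r in rows) / len(rows), 2),
        mean_gc_pct=round(sum(r.gc_pct for r in rows) / len(rows), 2),
    )


def stats_table(rows: Sequence[PoolStats], report: AggregateReport | None = None) -> pd.DataFrame:
    """Per-pool rows (plus a Total row when a report is given) as a DataFrame
    in the conventional column order."""
    df = pd.DataFrame(
        [
            {
                "Name": r.pool_id,
                "N. BACs": r.n_bacs,
                "Trimmed reads": r.trimmed_reads,
                "Host %": r.host_pct,
                "Contigs": r.n_contigs,
                "Longest contig": r.longest,
                "Smallest contig": r.smallest,
                "Contig total length": r.total_length,
                "N50": r.n50,
                "GC (%)": r.gc_pct,
            }
            for r in rows
        ]
    )
    if report is not None:
        total = {
            "Name": "Total",
            "N. BACs": report.total_bacs,
            "Trimmed reads": report.total_reads,
            "Host %": report.mean_host_pct,
            "Contigs": report.total_contigs,
            "Longest contig": report.max_longest,
            "Smallest contig": min(r.smallest for r in rows),
            "Contig total length": report.total_length,
            "N50": "",
            "GC (%)": report.mean_gc_pct,
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df
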