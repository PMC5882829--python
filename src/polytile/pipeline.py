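"""End-to-end orchestration: configuration, stage execution, reporting.

The pipeline chains the stages of targeted sequencing by gene synteny:
simulate (or load) a region -> design markers -> screen 3D pools ->
select double-positive clones -> plan conflict-free sequencing pools ->
simulate pool contigs -> QC -> synteny reconstruction.  Every random
stage derives its seed from the run seed, and a machine-readable run log
records config, seeds and per-stage record counts so any run can be
reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, qc, screening, simulate, synteny
from .genome import GenomicRegion, SequenceRecord, write_bed, write_fasta, write_gff3
from .markers import MarkerPair, design_markers
from .qc import Contig

log = logging.getLogger("polytile")

__all__ = ["RunConfig", "run_simulate", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """All stage parameters for a run; defaults are the study conditions."""

    seed: int = 0
    outdir: str = "polytile_out"
    # simulation
    sim: simulate.SimulationParams = field(default_factory=simulate.SimulationParams)
    # library
    n_clones: int = 400
    insert_mean_bp: int = 100_000
    insert_sd_bp: int = 15_000
    layout: tuple[int, int, int] = (5, 10, 10)
    # screening
    max_amplicon: int = 3_000
    max_mismatch: int = 3  # tolerant annealing so markers amplify across homeologs
    min_markers: int = 2
    pool_capacity: int = 8
    # pool sequencing / contigs
    error_rate: float = 0.01
    reads_per_clone: int = 60
    decoys_per_clone: float = 2.5
    pool_mean_coverage: float = 60.0
    # QC
    min_read_len: int = 500
    contig_min_len: int = 50_000
    coverage_frac: float = 0.25
    # synteny
    min_identity: float = 0.8
    min_cds_coverage: float = 0.5
    same_identity: float = 0.99
    same_aligned_frac: float = 0.95
    intergenic_frac_cutoff: float = 0.5
    max_homeolog_pairs: int = 200

    def validate(self) -> None:
        self.sim.validate()
        n_p, n_r, n_c = self.layout
        if self.n_clones > n_p * n_r * n_c:
            raise ValueError("n_clones exceeds layout capacity")
        if self.pool_capacity < 1:
            raise ValueError("pool_capacity must be >= 1")
        for name in ("max_mismatch", "min_markers", "min_read_len", "contig_min_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(simulate.SimulationParams)}
            sim_unknown = set(kwargs["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            sim_kwargs = dict(kwargs["sim"])
            for key in ("te_class_mix", "ltr_family_mix", "te_length_range"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            kwargs["sim"] = simulate.SimulationParams(**sim_kwargs)
        if "layout" in kwargs:
            kwargs["layout"] = tuple(kwargs["layout"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["layout"] = list(self.layout)
        for key in ("te_class_mix", "ltr_family_mix", "te_length_range"):
            d["sim"][key] = list(d["sim"][key])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _truth_table(truths: list[simulate.HomeologTruth]) -> list[str]:
    lines = ["homeolog\tref_gene_index\tpresent\tstart\tend\ttandem_dup"]
    for t in truths:
        for g in t.genes:
            s = g.interval.start if g.interval else ""
            e = g.interval.end if g.interval else ""
            lines.append(f"h{t.homeolog_id}\t{g.ref_index}\t{int(g.present)}\t{s}\t{e}\t{int(g.tandem_dup)}")
    return lines


def _truth_gff3(truths: list[simulate.HomeologTruth]) -> list[str]:
    lines = ["##gff-version 3"]
    for t in truths:
        chrom = f"h{t.homeolog_id}"
        for g in t.genes:
            if not g.present:
                continue
            iv = g.interval
            lines.append(
                f"{chrom}\tpolytile_sim\tgene\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID={chrom}.g{g.ref_index:03d};ref_index={g.ref_index}"
            )
            if g.tandem_dup and g.dup_interval:
                dv = g.dup_interval
                lines.append(
                    f"{chrom}\tpolytile_sim\tgene\t{dv.start + 1}\t{dv.end}\t.\t+\t.\t"
                    f"ID={chrom}.g{g.ref_index:03d}dup;ref_index={g.ref_index};tandem_dup=1"
                )
        for k, te in enumerate(t.te_insertions):
            iv = te.interval
            lines.append(
                f"{chrom}\tpolytile_sim\trepeat_region\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID={chrom}.te{k:04d};class={te.te_class};family={te.family}"
            )
    return lines


@dataclass
class SimulatedInputs:
    reference: GenomicRegion
    homeologs: list[SequenceRecord]
    truths: list[simulate.HomeologTruth]
    transcripts: list[SequenceRecord]
    library: simulate.BacLibrary


def build_inputs(config: RunConfig) -> SimulatedInputs:
    """Run the simulator stages for a config (in memory)."""
    seed = config.seed
    reference = simulate.simulate_reference_region(config.sim, seed)
    homeologs, truths = simulate.derive_homeologs(reference, config.sim, seed)
    transcripts = simulate.simulate_transcriptome(reference, truths, config.sim, seed)
    library = simulate.simulate_bac_library(
        homeologs,
        config.n_clones,
        config.insert_mean_bp,
        config.insert_sd_bp,
        config.layout,
        seed,
    )
    return SimulatedInputs(reference, homeologs, truths, transcripts, library)


def run_simulate(config: RunConfig, outdir: str | Path | None = None) -> dict[str, str]:
    """Write all simulator artifacts plus a checksum manifest; returns the
    manifest (relative path -> sha256)."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = build_inputs(config)

    with open(out / "reference.fasta", "w") as fh:
        write_fasta([SequenceRecord("ref", inputs.reference.sequence, "reference region")], fh)
    with open(out / "reference.gff3", "w") as fh:
        write_gff3(inputs.reference.genes, fh)
    with open(out / "homeologs.fasta", "w") as fh:
        write_fasta(inputs.homeologs, fh)
    with open(out / "transcripts.fasta", "w") as fh:
        write_fasta(inputs.transcripts, fh)
    (out / "truth.gff3").write_text("\n".join(_truth_gff3(inputs.truths)) + "\n")
    (out / "truth_table.tsv").write_text("\n".join(_truth_table(inputs.truths)) + "\n")
    lib_lines = ["clone_id\tplate\trow\tcol\thomeolog\tstart\tend"]
    for c in inputs.library.clones:
        p, r, col = c.address
        iv = c.source_interval
        lib_lines.append(f"{c.clone_id}\t{p}\t{r}\t{col}\t{iv.chrom}\t{iv.start}\t{iv.end}")
    (out / "library.tsv").write_text("\n".join(lib_lines) + "\n")

    manifest = {
        name: _sha256(out / name)
        for name in [
            "reference.fasta",
            "reference.gff3",
            "homeologs.fasta",
            "transcripts.fasta",
            "truth.gff3",
            "truth_table.tsv",
            "library.tsv",
        ]
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


@dataclass
class PipelineResult:
    markers: list[MarkerPair]
    clone_matrix: Any  # clone x marker boolean DataFrame
    selected: set[str]
    plan: screening.SequencingPoolPlan
    pool_stats: list[qc.PoolStats]
    aggregate: qc.AggregateReport
    kept_contigs: list[Contig]
    annotations: list[synteny.BacAnnotation]
    blocks: list[synteny.SyntenyBlock]
    gaps: list[tuple[int, int]]
    path: synteny.TilingPath
    clusters: list[set[str]]
    report: dict
    inputs: SimulatedInputs


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full synthetic pipeline and write stage outputs."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    inputs = build_inputs(config)
    run_log["stages"]["simulate"] = {
        "genes": len(inputs.reference.genes),
        "homeologs": len(inputs.homeologs),
        "transcripts": len(inputs.transcripts),
        "clones": len(inputs.library),
    }

    markers = design_markers(inputs.reference.genes, inputs.transcripts)
    run_log["stages"]["design_markers"] = {"markers": len(markers)}
    _write_markers(markers, out / "markers.tsv")

    design = screening.build_3d_pools(inputs.library)
    cm = screening.clone_marker_matrix(
        inputs.library.clones, markers, config.max_amplicon, config.max_mismatch
    )
    signals = screening.screen_pools(design, inputs.library, markers, clone_matrix=cm)
    signals.entries.to_csv(out / "pool_signals.tsv", sep="\t")
    confirmed = {}
    for m in markers:
        cand = screening.deconvolve(signals, design, m.marker_id)
        confirmed[m.marker_id] = screening.confirm_candidates(
            cand, m, inputs.library, config.max_amplicon, config.max_mismatch
        )
    selected = screening.select_bacs(confirmed, config.min_markers)
    run_log["stages"]["screen"] = {
        "pools": len(design.pools),
        "selected_clones": len(selected),
    }
    marker_map = {
        c: {m for m, clones in confirmed.items() if c in clones} for c in selected
    }
    plan = screening.plan_sequencing_pools(selected, marker_map, config.pool_capacity)
    violations = screening.verify_plan(plan, marker_map)
    if violations:
        raise RuntimeError(f"sequencing-pool plan violates constraints: {violations[:3]}")
    run_log["stages"]["plan_pools"] = {"sequencing_pools": plan.n_pools}
    _write_plan(plan, inputs.library, out / "sequencing_pools.tsv")

    # sequencing + assembly emulation, then QC, per sequencing pool
    by_id = {c.clone_id: c for c in inputs.library.clones}
    vector = simulate.default_vector()
    host = simulate.default_host()
    pool_stats: list[qc.PoolStats] = []
    all_contigs: list[Contig] = []
    for idx, members in enumerate(plan.pools()):
        pool_id = f"pool{idx:02d}"
        clones = [by_id[c] for c in members]
        reads, contigs = simulate.simulate_pool_contigs(
            clones,
            error_rate=config.error_rate,
            host_read_fraction=config.sim.host_read_fraction,
            vector=vector,
            host=host,
            seed=config.seed + 10_000 + idx,
            pool_id=pool_id,
            reads_per_clone=config.reads_per_clone,
            decoys_per_clone=config.decoys_per_clone,
            pool_mean_coverage=config.pool_mean_coverage,
        )
        kept_reads, host_pct, _ = qc.trim_and_decontaminate(
            reads, vector, host, min_len=config.min_read_len
        )
        pool_stats.append(
            qc.contig_stats(contigs, len(clones), len(kept_reads), round(host_pct, 2), pool_id)
        )
        all_contigs.extend(contigs)
    aggregate = qc.aggregate_report(pool_stats) if pool_stats else None
    kept_contigs, removed, pct_removed = qc.filter_contigs(
        all_contigs, config.contig_min_len, config.coverage_frac
    )
    if aggregate is not None:
        aggregate.n_filtered = len(removed)
        aggregate.pct_filtered = pct_removed
        qc.stats_table(pool_stats, aggregate).to_csv(out / "qc_table.tsv", sep="\t", index=False)
        (out / "qc_report.json").write_text(
            json.dumps(
                {"pools": [asdict(r) for r in pool_stats], "aggregate": asdict(aggregate)},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    run_log["stages"]["qc"] = {
        "pools": len(pool_stats),
        "contigs": len(all_contigs),
        "kept_contigs": len(kept_contigs),
        "pct_removed": pct_removed,
    }

    annotated = [
        synteny.AnnotatedBac(c, synteny.annotate_bac(c, inputs.reference, config.min_identity, config.min_cds_coverage))
        for c in kept_contigs
    ]
    annotations = [ab.annotation for ab in annotated]
    mapped = [ab for ab in annotated if ab.annotation.hits]
    calls = _pairwise_calls(mapped, config)
    clusters, warnings = synteny.group_homeologs(calls)
    for w in warnings:
        log.warning(w)
    tandem = sorted({g for ann in annotations for g in synteny.detect_tandem_dups(ann)})
    blocks, gaps = synteny.build_syntenic_blocks(annotations, clusters)
    path, path_warnings = synteny.minimal_tiling_path(annotated)
    for w in path_warnings:
        log.warning(w)
    report = synteny.region_report(blocks, path, annotations, tandem, clusters)
    run_log["stages"]["synteny"] = dict(report)

    _write_synteny(out, inputs.reference, annotations, blocks, path, clusters, report)
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        markers, cm, selected, plan, pool_stats, aggregate, kept_contigs,
        annotations, blocks, gaps, path, clusters, report, inputs,
    )


def _pairwise_calls(mapped: list[synteny.AnnotatedBac], config: RunConfig) -> list[synteny.HomeologCall]:
    pairs = []
    for i, a in enumerate(mapped):
        for b in mapped[i + 1 :]:
            ra, rb = a.annotation.mapped_range, b.annotation.mapped_range
            if ra and rb and ra[0] <= rb[1] and rb[0] <= ra[1]:
                pairs.append((a, b))
    if len(pairs) > config.max_homeolog_pairs:
        rng = np.random.default_rng(config.seed + 77)
        idx = rng.choice(len(pairs), size=config.max_homeolog_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return [
        synteny.classify_homeolog_pair(
            a, b, config.same_identity, config.same_aligned_frac,
            config.intergenic_frac_cutoff, config.min_identity,
        )
        for a, b in pairs
    ]


def _write_markers(markers: list[MarkerPair], path: Path) -> None:
    lines = ["marker_id\tgene_id\tforward\treverse\ttm_f\ttm_r\tgc_f\tgc_r\tamplicon_bp"]
    for m in markers:
        lines.append(
            f"{m.marker_id}\t{m.gene_id}\t{m.forward}\t{m.reverse}\t{m.tm_f}\t{m.tm_r}\t{m.gc_f}\t{m.gc_r}\t{m.expected_amplicon_bp}"
        )
    path.write_text("\n".join(lines) + "\n")
    primers = []
    for m in markers:
        primers.append(SequenceRecord(f"{m.marker_id}_F", m.forward, m.gene_id))
        primers.append(SequenceRecord(f"{m.marker_id}_R", m.reverse, m.gene_id))
    with open(path.with_suffix(".fasta"), "w") as fh:
        write_fasta(primers, fh)


def _write_plan(plan: screening.SequencingPoolPlan, library: simulate.BacLibrary, path: Path) -> None:
    by_id = {c.clone_id: c for c in library.clones}
    lines = ["clone_id\tplate\trow\tcol\tsequencing_pool"]
    for clone_id, idx in sorted(plan.assignment.items()):
        p, r, c = by_id[clone_id].address
        lines.append(f"{clone_id}\t{p}\t{r}\t{c}\t{idx}")
    path.write_text("\n".join(lines) + "\n")


def _write_synteny(out, reference, annotations, blocks, path, clusters, report) -> None:
    gff = ["##gff-version 3"]
    for ann in annotations:
        for k, h in enumerate(ann.hits):
            iv = h.bac_interval
            gene = reference.genes[h.reference_gene_index]
            gff.append(
                f"{ann.bac_id}\tpolytile\tmatch\t{iv.start + 1}\t{iv.end}\t{h.identity:.3f}\t{h.strand}\t.\t"
                f"ID={ann.bac_id}.hit{k};Target={gene.gene_id};ref_index={h.reference_gene_index}"
            )
    (out / "bac_annotations.gff3").write_text("\n".join(gff) + "\n")
    from .genome import CoordinateInterval

    with open(out / "syntenic_blocks.bed", "w") as fh:
        write_bed(
            (
                (
                    CoordinateInterval(
                        reference.interval.chrom,
                        reference.genes[b.start_index].interval.start,
                        reference.genes[b.end_index].interval.end,
                    ),
                    f"block{i:02d}",
                )
                for i, b in enumerate(blocks)
            ),
            fh,
        )
    ann_by_id = {a.bac_id: a for a in annotations}
    with open(out / "tiling_path.bed", "w") as fh:
        entries = []
        for bac_id in path.bac_ids:
            r = ann_by_id[bac_id].mapped_range
            entries.append(
                (
                    CoordinateInterval(
                        reference.interval.chrom,
                        reference.genes[r[0]].interval.start,
                        reference.genes[r[1]].interval.end,
                    ),
                    bac_id,
                )
            )
        write_bed(entries, fh)
    cl_lines = ["cluster\tbac_id"]
    for i, cl in enumerate(clusters):
        for bac in sorted(cl):
            cl_lines.append(f"{i}\t{bac}")
    (out / "homeolog_clusters.tsv").write_text("\n".join(cl_lines) + "\n")
    (out / "synteny_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
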