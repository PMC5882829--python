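"""Ground-truth validation runs over the synthetic study conditions.

Two standard evaluations are provided:

* :func:`simulation_recovery` — a scaled polyploid simulation (4 homeologs,
  61 genes, 400 clones) pushed through marker design, 3D-pool screening,
  selection and annotation, with every recovered quantity compared against
  the simulator's ground truth.
* :func:`degenerate_limit` — the zero-divergence / zero-repeat limit in
  which the pipeline must reconstruct the reference exactly: one syntenic
  block, no gaps, a tiling path covering every reference gene.

Both are deterministic given a seed and are what the acceptance script
reports.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import screening, simulate, synteny
from .markers import design_markers
from .qc import Contig

__all__ = ["simulation_recovery", "degenerate_limit", "RECOVERY_PARAMS", "DEGENERATE_PARAMS"]

# Scaled study conditions: the full gene complement and divergence structure
# at 4 homeologs / 400 clones, which keeps a desk-scale runtime.
RECOVERY_PARAMS = simulate.SimulationParams(ploidy=4)
RECOVERY_N_CLONES = 400
RECOVERY_LAYOUT = (5, 10, 10)

DEGENERATE_PARAMS = simulate.SimulationParams(
    n_genes=30,
    region_length_bp=200_000,
    ploidy=2,
    genic_divergence=0.0,
    intergenic_divergence=0.0,
    repeat_fraction_target=0.0,
    n_tandem_dup_genes=0,
    transcript_detect_count=30,
    gene_loss_rate=0.0,
)
DEGENERATE_N_CLONES = 120
DEGENERATE_LAYOUT = (2, 8, 8)


def _screen_and_select(library, markers, max_mismatch, min_markers=2):
    """3D screening -> deconvolution -> confirmation -> double-positive
    selection, reusing one clone x marker PCR matrix throughout."""
    cm = screening.clone_marker_matrix(library.clones, markers, max_mismatch=max_mismatch)
    design = screening.build_3d_pools(library)
    signals = screening.screen_pools(design, library, markers, clone_matrix=cm)
    confirmed = {}
    for m in markers:
        candidates = screening.deconvolve(signals, design, m.marker_id)
        amplifying = set(cm.index[cm[m.marker_id]])
        confirmed[m.marker_id] = candidates & amplifying  # per-clone confirmation PCR
    selected = screening.select_bacs(confirmed, min_markers)
    return cm, confirmed, selected


def simulation_recovery(
    seed: int,
    params: simulate.SimulationParams | None = None,
    n_clones: int = RECOVERY_N_CLONES,
    layout: tuple[int, int, int] = RECOVERY_LAYOUT,
    max_mismatch: int = 3,
    n_pairs: int = 150,
) -> dict:
    """Recovery metrics of the screening + synteny stages against truth."""
    params = replace(params if params is not None else RECOVERY_PARAMS, seed=seed)
    reference = simulate.simulate_reference_region(params)
    homeologs, truths = simulate.derive_homeologs(reference, params)
    transcripts = simulate.simulate_transcriptome(reference, truths, params)
    markers = design_markers(reference.genes, transcripts)
    library = simulate.simulate_bac_library(homeologs, n_clones, layout=layout, seed=seed)

    cm, confirmed, selected = _screen_and_select(library, markers, max_mismatch)
    # the selection must be exactly the clones whose own insert amplifies
    # >= 2 distinct markers (direct per-clone PCR is the reference standard)
    expected = set(cm.index[(cm.sum(axis=1) >= 2)])
    marker_map = {c: {m for m, cl in confirmed.items() if c in cl} for c in selected}
    plan = screening.plan_sequencing_pools(selected, marker_map)
    plan_violations = screening.verify_plan(plan, marker_map)

    # interval-level agreement: markers whose source-gene copy overlaps the
    # clone insert (reported, not an exactness requirement: amplification at
    # an insert edge legitimately differs from whole-gene containment)
    marker_gidx = {m.marker_id: int(m.gene_id[1:]) for m in markers}
    n_agree = 0
    for clone in library.clones:
        truth = truths[clone.source_homeolog]
        src = clone.source_interval
        n_truth = 0
        for g in truth.genes:
            if not g.present or g.ref_index not in set(marker_gidx.values()):
                continue
            if g.interval.start < src.end and src.start < g.interval.end:
                n_truth += 1
        if (n_truth >= 2) == (clone.clone_id in selected):
            n_agree += 1
    interval_agreement = n_agree / len(library.clones)

    # annotate every clone insert (error-free contig stand-ins)
    annotated = []
    for clone in library.clones:
        contig = Contig(clone.clone_id, clone.insert_sequence, 50.0, "sim")
        ann = synteny.annotate_bac(contig, reference)
        annotated.append(synteny.AnnotatedBac(contig, ann))

    # tandem duplications: recovered iff detected on >= 1 clone; a detection
    # of a gene the simulator did not duplicate is a false positive
    truth_dups = {g.ref_index for t in truths for g in t.genes if g.tandem_dup}
    detected_dups: set[int] = set()
    for ab in annotated:
        detected_dups |= set(synteny.detect_tandem_dups(ab.annotation))
    false_positives = detected_dups - truth_dups
    recovered = detected_dups & truth_dups
    # a duplication is only recoverable if some insert spans both copies
    recoverable = set()
    for t in truths:
        for g in t.genes:
            if not g.tandem_dup:
                continue
            for clone in library.clones:
                if clone.source_homeolog != t.homeolog_id:
                    continue
                src = clone.source_interval
                if src.start <= g.interval.start and g.dup_interval.end <= src.end:
                    recoverable.add(g.ref_index)
                    break

    # homeolog pair classification over a sample of overlapping pairs
    mapped = [ab for ab in annotated if ab.annotation.hits]
    by_id = {c.clone_id: c for c in library.clones}
    pairs = []
    for i, a in enumerate(mapped):
        for b in mapped[i + 1 :]:
            ra, rb = a.annotation.mapped_range, b.annotation.mapped_range
            if ra[0] <= rb[1] and rb[0] <= ra[1]:
                pairs.append((a, b))
    rng = np.random.default_rng([seed, 9_001])
    if len(pairs) > n_pairs:
        idx = rng.choice(len(pairs), size=n_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    n_correct = 0
    for a, b in pairs:
        call = synteny.classify_homeolog_pair(a, b)
        truth_verdict = (
            "same" if by_id[a.bac_id].source_homeolog == by_id[b.bac_id].source_homeolog else "different"
        )
        if call.verdict == truth_verdict:
            n_correct += 1

    return {
        "n_genes": len(reference.genes),
        "n_markers": len(markers),
        "n_clones": len(library.clones),
        "n_selected": len(selected),
        "selection_matches_per_clone_pcr": selected == expected,
        "selection_interval_agreement": interval_agreement,
        "plan_n_pools": plan.n_pools,
        "plan_violations": len(plan_violations),
        "repeat_fraction": float(np.mean([t.repeat_fraction() for t in truths])),
        "tandem_dups_planted": len(truth_dups),
        "tandem_dups_recoverable": len(recoverable),
        "tandem_dups_recovered": len(recovered),
        "tandem_dup_false_positives": len(false_positives),
        "homeolog_pairs_evaluated": len(pairs),
        "homeolog_accuracy": (n_correct / len(pairs)) if pairs else float("nan"),
    }


def degenerate_limit(
    seed: int,
    params: simulate.SimulationParams | None = None,
    n_clones: int = DEGENERATE_N_CLONES,
    layout: tuple[int, int, int] = DEGENERATE_LAYOUT,
) -> dict:
    """Zero-divergence, zero-repeat, full-transcript-detection limit."""
    params = replace(params if params is not None else DEGENERATE_PARAMS, seed=seed)
    reference = simulate.simulate_reference_region(params)
    homeologs, truths = simulate.derive_homeologs(reference, params)
    transcripts = simulate.simulate_transcriptome(reference, truths, params)
    markers = design_markers(reference.genes, transcripts)
    library = simulate.simulate_bac_library(
        homeologs, n_clones, insert_mean_bp=40_000, insert_sd_bp=6_000, layout=layout, seed=seed
    )
    _, confirmed, selected = _screen_and_select(library, markers, max_mismatch=0)

    by_id = {c.clone_id: c for c in library.clones}
    annotated = []
    for clone_id in sorted(selected):
        clone = by_id[clone_id]
        contig = Contig(clone.clone_id, clone.insert_sequence, 50.0, "sim")
        annotated.append(synteny.AnnotatedBac(contig, synteny.annotate_bac(contig, reference)))
    collinear_flags = [synteny.map_to_reference(ab.annotation)[1] for ab in annotated]
    blocks, gaps = synteny.build_syntenic_blocks([ab.annotation for ab in annotated])
    path, warnings = synteny.minimal_tiling_path(annotated)
    covered = set()
    for ab in annotated:
        covered |= ab.annotation.gene_indices
    path_ids = set(path.bac_ids)
    path_covered = set()
    for ab in annotated:
        if ab.bac_id in path_ids:
            path_covered |= ab.annotation.gene_indices
    return {
        "n_markers": len(markers),
        "n_selected": len(selected),
        "all_collinear": all(collinear_flags),
        "n_blocks": len(blocks),
        "n_gaps": len(gaps),
        "covered_equals_reference": covered == set(range(len(reference.genes))),
        "path_covers_union": path_covered == covered,
        "n_tiling_bacs": len(path.bac_ids),
        "tiling_total_bp": path.total_bp,
    }
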