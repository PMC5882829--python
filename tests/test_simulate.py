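"""Polyploid simulator: determinism, ground-truth bookkeeping, and the
statistical structure of the synthetic region."""

import numpy as np
import pytest

from polytile import simulate
from polytile.simulate import (
    SimulationParams,
    derive_homeologs,
    simulate_bac_library,
    simulate_pool_contigs,
    simulate_reference_region,
    simulate_transcriptome,
)


class TestParams:
    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_genes=0).validate()

    def test_detect_count_above_n_genes_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_genes=10, transcript_detect_count=11).validate()

    def test_te_mix_renormalizes(self):
        p = SimulationParams()
        assert p.te_class_probs.sum() == pytest.approx(1.0)
        assert p.ltr_family_probs.sum() == pytest.approx(1.0)


class TestReferenceRegion:
    def test_gene_count_order_and_structure(self):
        p = SimulationParams(seed=1)
        region = simulate_reference_region(p)
        assert len(region.genes) == 61
        starts = [g.interval.start for g in region.genes]
        assert starts == sorted(starts)
        prev_end = 0
        for g in region.genes:
            assert g.interval.start >= prev_end  # non-overlapping
            prev_end = g.interval.end
            assert len(g.cds_sequence) == sum(len(e) for e in g.exons)

    def test_deterministic_for_seed(self):
        p = SimulationParams(
            n_genes=8, region_length_bp=40_000, transcript_detect_count=8, n_tandem_dup_genes=2, seed=5
        )
        a = simulate_reference_region(p)
        b = simulate_reference_region(p)
        assert a.sequence == b.sequence
        assert [g.interval for g in a.genes] == [g.interval for g in b.genes]

    def test_region_too_small(self):
        with pytest.raises(ValueError):
            simulate_reference_region(SimulationParams(n_genes=61, region_length_bp=10_000))


class TestHomeologs:
    def test_zero_rate_limit_identical_to_reference(self):
        p = SimulationParams(
            n_genes=6,
            region_length_bp=30_000,
            ploidy=2,
            genic_divergence=0.0,
            intergenic_divergence=0.0,
            repeat_fraction_target=0.0,
            n_tandem_dup_genes=0,
            transcript_detect_count=6,
            gene_loss_rate=0.0,
            seed=2,
        )
        region = simulate_reference_region(p)
        homeologs, truths = derive_homeologs(region, p)
        assert len(homeologs) == 2
        for h, t in zip(homeologs, truths):
            assert h.sequence == region.sequence
            assert t.te_insertions == []
            for g, gene in zip(t.genes, region.genes):
                assert g.present
                assert (g.interval.start, g.interval.end) == (gene.interval.start, gene.interval.end)

    def test_repeat_fraction_hits_target(self):
        p = SimulationParams(seed=7)
        region = simulate_reference_region(p)
        _, truths = derive_homeologs(region, p)
        for t in truths:
            assert 0.48 <= t.repeat_fraction() <= 0.54

    def test_tandem_dup_count(self):
        p = SimulationParams(seed=7)
        region = simulate_reference_region(p)
        _, truths = derive_homeologs(region, p)
        flagged = {g.ref_index for t in truths for g in t.genes if g.tandem_dup}
        assert len(flagged) == 6
        for t in truths:
            for g in t.genes:
                if g.tandem_dup:
                    assert g.present and g.dup_interval is not None
                    assert g.dup_interval.start >= g.interval.end

    def test_collinearity_preserved(self, toy_sim):
        for t in toy_sim["truths"]:
            order = t.surviving_order()
            assert order == sorted(order)

    def test_te_class_proportions(self):
        p = SimulationParams(seed=7)
        region = simulate_reference_region(p)
        _, truths = derive_homeologs(region, p)
        counts = {"LTR": 0, "DNA": 0, "nonLTR": 0}
        for t in truths:
            for te in t.te_insertions:
                counts[te.te_class] += 1
        total = sum(counts.values())
        probs = p.te_class_probs
        for cls, expected in zip(("LTR", "DNA", "nonLTR"), probs):
            assert abs(counts[cls] / total - expected) <= 0.10

    def test_te_lengths_within_range(self, toy_sim):
        lo, hi = toy_sim["params"].te_length_range
        for t in toy_sim["truths"]:
            for te in t.te_insertions:
                assert lo * 0.9 <= len(te.interval) <= hi * 1.1  # indel-free copies +- mutation

    def test_deterministic(self, toy_params):
        region = simulate_reference_region(toy_params)
        h1, _ = derive_homeologs(region, toy_params)
        h2, _ = derive_homeologs(region, toy_params)
        assert [h.sequence for h in h1] == [h.sequence for h in h2]


class TestTranscriptome:
    def test_detect_count_subset(self):
        p = SimulationParams(seed=3)
        region = simulate_reference_region(p)
        tx = simulate_transcriptome(region, None, p)
        assert len(tx) == 53  # 8 of the 61 genes stay undetected

    def test_full_and_empty_detection(self):
        p = SimulationParams(n_genes=10, region_length_bp=50_000, transcript_detect_count=10, seed=3)
        region = simulate_reference_region(p)
        assert len(simulate_transcriptome(region, None, p)) == 10
        p0 = SimulationParams(n_genes=10, region_length_bp=50_000, transcript_detect_count=0, seed=3)
        assert simulate_transcriptome(region, None, p0) == []


class TestBacLibrary:
    def test_capacity_error(self, toy_sim):
        with pytest.raises(ValueError):
            simulate_bac_library(toy_sim["homeologs"], 1_000, layout=(2, 5, 5))

    def test_empty_library(self, toy_sim):
        lib = simulate_bac_library(toy_sim["homeologs"], 0)
        assert len(lib) == 0

    def test_insert_length_distribution(self, toy_sim):
        lib = simulate_bac_library(
            toy_sim["homeologs"], 200, insert_mean_bp=20_000, insert_sd_bp=3_000, layout=(2, 10, 10), seed=3
        )
        lengths = np.array([len(c.insert_sequence) for c in lib.clones])
        assert abs(lengths.mean() - 20_000) <= 3 * 3_000 / np.sqrt(200)
        assert lengths.min() >= 10_000 and lengths.max() <= 40_000

    def test_inserts_within_bounds_and_addresses_unique(self, toy_sim):
        lib = simulate_bac_library(toy_sim["homeologs"], 40, insert_mean_bp=16_000, layout=(2, 5, 5), seed=1)
        addresses = {c.address for c in lib.clones}
        assert len(addresses) == 40
        for c in lib.clones:
            hom = toy_sim["homeologs"][c.source_homeolog]
            assert 0 <= c.source_interval.start < c.source_interval.end <= len(hom.sequence)
            assert c.insert_sequence == hom.sequence[c.source_interval.start : c.source_interval.end]


class TestPoolContigs:
    def test_empty_pool(self):
        assert simulate_pool_contigs([]) == ([], [])

    def test_zero_noise_limit(self, toy_sim):
        clones = toy_sim["library"].clones[:3]
        reads, contigs = simulate_pool_contigs(
            clones, error_rate=0.0, host_read_fraction=0.0, decoys_per_clone=0.0, seed=4,
            reads_per_clone=5,
        )
        assert [c.sequence for c in contigs] == [c.insert_sequence for c in clones]
        assert not any(r.description == "host" for r in reads)

    def test_host_fraction_planted(self, toy_sim):
        clones = toy_sim["library"].clones[:8]
        reads, _ = simulate_pool_contigs(
            clones, host_read_fraction=0.0825, reads_per_clone=1_250, seed=5
        )
        frac = sum(1 for r in reads if r.description == "host") / len(reads)
        assert abs(frac - 0.0825) <= 0.01

    def test_contig_count_and_short_fraction(self, toy_sim):
        clones = toy_sim["library"].clones[:8]
        _, contigs = simulate_pool_contigs(clones, seed=6)
        assert len(contigs) >= 8
        short = sum(1 for c in contigs if len(c) < 50_000)
        # toy inserts are 16 kb, so every contig is "short"; just check decoys exist
        assert len(contigs) == 8 + round(2.5 * 8)

    def test_deterministic(self, toy_sim):
        clones = toy_sim["library"].clones[:4]
        r1, c1 = simulate_pool_contigs(clones, seed=9)
        r2, c2 = simulate_pool_contigs(clones, seed=9)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert [c.sequence for c in c1] == [c.sequence for c in c2]
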