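"""Synteny reconstruction: annotation, homeolog calls, blocks, tiling path."""

import itertools
import random

import pytest

from polytile.genome import CoordinateInterval
from polytile.qc import Contig
from polytile.synteny import (
    AnnotatedBac,
    BacAnnotation,
    GeneHit,
    annotate_bac,
    build_syntenic_blocks,
    classify_homeolog_pair,
    detect_tandem_dups,
    group_homeologs,
    map_to_reference,
    minimal_tiling_path,
    region_report,
)


def _hit(gidx, start, end, strand="+", identity=1.0, bac="b"):
    return GeneHit(gidx, CoordinateInterval(bac, start, end, strand), identity, strand)


def _ann(bac_id, gene_indices, strand="+"):
    hits = [_hit(g, 100 + i * 1_000, 600 + i * 1_000, strand, bac=bac_id) for i, g in enumerate(gene_indices)]
    return BacAnnotation(bac_id, hits)


def _annotated(bac_id, gene_indices, length=10_000):
    return AnnotatedBac(Contig(bac_id, "A" * length, 50.0, "p"), _ann(bac_id, gene_indices))


class TestAnnotateBac:
    def test_verbatim_reference_slice(self, toy_sim):
        ref = toy_sim["reference"]
        # slice spanning genes 3..5 exactly
        start = ref.genes[3].interval.start - 50
        end = ref.genes[5].interval.end + 50
        bac = Contig("slice", ref.sequence[start:end], 50.0, "p")
        ann = annotate_bac(bac, ref)
        assert sorted(ann.gene_indices) == [3, 4, 5]
        assert all(h.identity == 1.0 for h in ann.hits)
        assert ann.orientation == "forward"

    def test_no_genes_above_threshold(self, toy_sim):
        rng = random.Random(0)
        bac = Contig("rand", "".join(rng.choice("ACGT") for _ in range(20_000)), 50.0, "p")
        assert annotate_bac(bac, toy_sim["reference"]).hits == []

    def test_homeolog_bac_recovers_truth_gene_content(self, toy_sim):
        lib, truths = toy_sim["library"], toy_sim["truths"]
        checked = 0
        for clone in lib.clones[:6]:
            truth = truths[clone.source_homeolog]
            src = clone.source_interval
            expected = {
                g.ref_index
                for g in truth.genes
                if g.present and g.interval.start >= src.start and g.interval.end <= src.end
            }
            ann = annotate_bac(Contig(clone.clone_id, clone.insert_sequence, 50.0, "p"), toy_sim["reference"])
            assert expected <= ann.gene_indices
            checked += 1
        assert checked == 6


class TestMapToReference:
    def test_forward_collinear(self):
        rng, coll = map_to_reference(_ann("b", [4, 5, 6]))
        assert rng == (4, 6) and coll

    def test_reverse_collinear(self):
        rng, coll = map_to_reference(_ann("b", [6, 5, 4]))
        assert rng == (4, 6) and coll

    def test_out_of_order_flagged(self):
        _, coll = map_to_reference(_ann("b", [4, 6, 5]))
        assert not coll

    def test_tandem_repeat_collapsed(self):
        _, coll = map_to_reference(_ann("b", [4, 4, 5, 6]))
        assert coll

    def test_empty_annotation(self):
        rng, coll = map_to_reference(BacAnnotation("b", []))
        assert rng is None and coll


class TestClassifyHomeologPair:
    def test_identical_sequences_same(self, toy_sim):
        ref = toy_sim["reference"]
        start, end = ref.genes[2].interval.start - 100, ref.genes[5].interval.end + 100
        seq = ref.sequence[start:end]
        a = AnnotatedBac(Contig("a", seq, 50.0, "p"), annotate_bac(Contig("a", seq, 50.0, "p"), ref))
        b = AnnotatedBac(Contig("b", seq, 50.0, "p"), annotate_bac(Contig("b", seq, 50.0, "p"), ref))
        call = classify_homeolog_pair(a, b)
        assert call.verdict == "same"
        assert call.overlap_identity == pytest.approx(1.0)

    def test_disjoint_ranges_unrelated(self):
        a = _annotated("a", [0, 1, 2, 3])
        b = _annotated("b", [10, 11, 12])
        assert classify_homeolog_pair(a, b).verdict == "unrelated"

    def test_different_homeologs_called_different(self, toy_sim):
        ref, truths, lib = toy_sim["reference"], toy_sim["truths"], toy_sim["library"]
        # find two clones from different homeologs with overlapping gene ranges
        pairs_checked = 0
        annotated = {}
        for c1, c2 in itertools.combinations(lib.clones[:20], 2):
            if c1.source_homeolog == c2.source_homeolog:
                continue
            for c in (c1, c2):
                if c.clone_id not in annotated:
                    contig = Contig(c.clone_id, c.insert_sequence, 50.0, "p")
                    annotated[c.clone_id] = AnnotatedBac(contig, annotate_bac(contig, ref))
            a, b = annotated[c1.clone_id], annotated[c2.clone_id]
            ra, rb = a.annotation.mapped_range, b.annotation.mapped_range
            if not (ra and rb and ra[0] <= rb[1] and rb[0] <= ra[1]):
                continue
            assert classify_homeolog_pair(a, b).verdict == "different"
            pairs_checked += 1
            if pairs_checked >= 3:
                break
        assert pairs_checked >= 1


class TestGroupHomeologs:
    def test_transitive_components(self):
        from polytile.synteny import HomeologCall

        calls = [
            HomeologCall("a", "b", "same"),
            HomeologCall("b", "c", "same"),
            HomeologCall("d", "e", "different"),
        ]
        clusters, warnings = group_homeologs(calls)
        assert {frozenset(c) for c in clusters} == {
            frozenset({"a", "b", "c"}),
            frozenset({"d"}),
            frozenset({"e"}),
        }
        assert warnings == []

    def test_conflicting_calls_warn_and_same_wins(self):
        from polytile.synteny import HomeologCall

        calls = [HomeologCall("a", "b", "same"), HomeologCall("a", "b", "different")]
        clusters, warnings = group_homeologs(calls)
        assert {frozenset(c) for c in clusters} == {frozenset({"a", "b"})}
        assert len(warnings) == 1


class TestDetectTandemDups:
    def test_adjacent_same_gene(self):
        assert detect_tandem_dups(_ann("b", [7, 7, 8])) == [7]

    def test_non_adjacent_not_tandem(self):
        assert detect_tandem_dups(_ann("b", [7, 8, 7])) == []

    def test_opposite_strand_not_tandem(self):
        hits = [
            _hit(7, 100, 600, "+"),
            _hit(7, 700, 1_200, "-"),
        ]
        assert detect_tandem_dups(BacAnnotation("b", hits)) == []

    def test_planted_duplication_recovered(self, toy_sim):
        ref, truths, lib = toy_sim["reference"], toy_sim["truths"], toy_sim["library"]
        recovered = set()
        truth_dups = {g.ref_index for t in truths for g in t.genes if g.tandem_dup}
        for t in truths:
            for g in t.genes:
                if not g.tandem_dup:
                    continue
                for clone in lib.clones:
                    if clone.source_homeolog != t.homeolog_id:
                        continue
                    src = clone.source_interval
                    if src.start <= g.interval.start and g.dup_interval.end <= src.end:
                        ann = annotate_bac(
                            Contig(clone.clone_id, clone.insert_sequence, 50.0, "p"), ref
                        )
                        recovered |= set(detect_tandem_dups(ann))
                        break
        assert recovered <= truth_dups  # zero false positives among these clones
        assert len(recovered) >= 1


class TestSyntenicBlocks:
    def test_two_blocks_one_gap(self):
        anns = [_ann("a", [1, 2, 3]), _ann("b", [3, 4, 5]), _ann("c", [8, 9, 10])]
        blocks, gaps = build_syntenic_blocks(anns)
        assert [(b.start_index, b.end_index) for b in blocks] == [(1, 5), (8, 10)]
        assert gaps == [(6, 7)]

    def test_full_coverage_single_block(self):
        blocks, gaps = build_syntenic_blocks([_ann("a", list(range(10)))])
        assert len(blocks) == 1 and gaps == []

    def test_four_blocks_three_gaps(self):
        anns = [_ann(f"b{i}", idx) for i, idx in enumerate([[0, 1], [4], [7, 8], [11, 12, 13]])]
        blocks, gaps = build_syntenic_blocks(anns)
        assert len(blocks) == 4 and len(gaps) == 3

    def test_contributing_bacs_recorded(self):
        anns = [_ann("a", [1, 2]), _ann("b", [2, 3]), _ann("c", [9])]
        blocks, _ = build_syntenic_blocks(anns)
        assert blocks[0].bac_ids == ["a", "b"] and blocks[1].bac_ids == ["c"]


def _brute_force_min_cover(annotated):
    covered = set()
    for ab in annotated:
        covered |= ab.annotation.gene_indices
    for size in range(0, len(annotated) + 1):
        for subset in itertools.combinations(annotated, size):
            union = set()
            for ab in subset:
                union |= ab.annotation.gene_indices
            if union == covered:
                return size
    return len(annotated)


class TestMinimalTilingPath:
    def test_nested_interval_collapses(self):
        x = _annotated("x", list(range(0, 10)))
        y = _annotated("y", list(range(2, 6)))
        path, warnings = minimal_tiling_path([x, y])
        assert path.bac_ids == ["x"] and warnings == []

    def test_two_disjoint_blocks(self):
        path, _ = minimal_tiling_path([_annotated("a", [0, 1]), _annotated("b", [5, 6])])
        assert len(path.block_paths) == 2 and path.bac_ids == ["a", "b"]

    def test_non_collinear_excluded_with_warning(self):
        good = _annotated("good", [0, 1, 2])
        bad = AnnotatedBac(Contig("bad", "A" * 1_000, 50.0, "p"), _ann("bad", [0, 2, 1]))
        path, warnings = minimal_tiling_path([good, bad])
        assert path.bac_ids == ["good"]
        assert any("bad" in w for w in warnings)

    def test_total_bp_is_sum_of_chosen_lengths(self):
        a = _annotated("a", [0, 1, 2], length=7_000)
        b = _annotated("b", [2, 3, 4], length=9_000)
        path, _ = minimal_tiling_path([a, b])
        assert path.total_bp == 16_000

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_minimum(self, seed):
        rng = random.Random(seed)
        n_genes = rng.randint(4, 14)
        bacs = []
        for i in range(rng.randint(2, 8)):
            s = rng.randrange(n_genes)
            e = rng.randrange(s, min(s + 6, n_genes))
            bacs.append(_annotated(f"b{i:02d}", list(range(s, e + 1)), length=rng.randint(1_000, 9_000)))
        path, _ = minimal_tiling_path(bacs)
        assert len(path.bac_ids) == _brute_force_min_cover(bacs)
        union = set()
        for ab in bacs:
            union |= ab.annotation.gene_indices
        path_union = set()
        ids = set(path.bac_ids)
        for ab in bacs:
            if ab.bac_id in ids:
                path_union |= ab.annotation.gene_indices
        assert path_union == union


class TestRegionReport:
    def test_empty_inputs(self):
        from polytile.synteny import TilingPath

        rep = region_report([], TilingPath([], 0), [])
        assert rep["n_mapped_bacs"] == 0 and rep["genes_covered"] == 0

    def test_counts_recomputed_from_inputs(self):
        anns = [_ann("a", [0, 1, 2]), _ann("b", [2, 3])]
        blocks, gaps = build_syntenic_blocks(anns)
        path, _ = minimal_tiling_path([_annotated("a", [0, 1, 2]), _annotated("b", [2, 3])])
        rep = region_report(blocks, path, anns, tandem_dups=[1], clusters=[{"a"}, {"b"}])
        assert rep["genes_covered"] == 4
        assert rep["n_blocks"] == 1 and rep["n_gaps"] == 0
        assert rep["n_tandem_dup_genes"] == 1
        assert rep["n_homeolog_clusters"] == 2
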