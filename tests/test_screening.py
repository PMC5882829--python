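"""3D pooling, in-silico PCR, deconvolution, selection and pool planning."""

import itertools
import random

import pandas as pd
import pytest

from polytile.align import revcomp
from polytile.genome import CoordinateInterval
from polytile.markers import MarkerPair
from polytile.screening import (
    PoolDesign,
    PoolSignalMatrix,
    build_3d_pools,
    clone_marker_matrix,
    confirm_candidates,
    deconvolve,
    insilico_pcr,
    plan_sequencing_pools,
    screen_pools,
    select_bacs,
    verify_plan,
)
from polytile.simulate import BacClone, BacLibrary


def _marker(forward="ACGTTGCAACGTTGCAACGT", reverse="TGCAACGTTGCAACGTTGCA", mid="m1", gene="g1"):
    return MarkerPair(mid, gene, forward, reverse, 60.0, 60.0, 50.0, 50.0, 300)


def _clone(clone_id, address, seq, hom=0, start=0):
    return BacClone(clone_id, address, hom, CoordinateInterval("h0", start, start + len(seq)), seq)


def _library(clones, layout):
    return BacLibrary(clones, layout)


def amplifiable(marker, filler=300):
    return marker.forward + "A" * filler + revcomp(marker.reverse)


class TestBuild3dPools:
    def test_2x2x2_layout(self):
        clones = [
            _clone(f"c{i}", (p, r, c), "ACGT")
            for i, (p, r, c) in enumerate(itertools.product(range(2), repeat=3))
        ]
        design = build_3d_pools(_library(clones, (2, 2, 2)))
        assert len(design.pools) == 6
        for clone in clones:
            assert sum(clone.clone_id in members for members in design.pools.values()) == 3

    def test_single_clone(self):
        design = build_3d_pools(_library([_clone("c0", (0, 0, 0), "ACGT")], (1, 1, 1)))
        assert all("c0" in members for members in design.pools.values())

    def test_axis_unions_cover_all_clones(self):
        clones = [_clone(f"c{i}", (i // 4, (i % 4) // 2, i % 2), "ACGT") for i in range(8)]
        design = build_3d_pools(_library(clones, (2, 2, 2)))
        for axis in design.axes:
            union = set().union(*(design.pools[p] for p in axis))
            assert union == {c.clone_id for c in clones}


class TestInsilicoPcr:
    def test_single_amplicon(self):
        m = _marker()
        template = "T" * 50 + amplifiable(m) + "T" * 50
        amps = insilico_pcr(template, m)
        assert len(amps) == 1
        i, j = amps[0]
        assert j - i == len(m.forward) + 300 + len(m.reverse)

    def test_absent_primers(self):
        assert insilico_pcr("A" * 500, _marker()) == []

    def test_two_forward_sites_match_brute_force(self):
        m = _marker()
        template = m.forward + "A" * 100 + m.forward + "A" * 100 + revcomp(m.reverse)
        amps = insilico_pcr(template, m, both_orientations=False)
        # brute-force position scan
        fl, rl = len(m.forward), len(m.reverse)
        rc = revcomp(m.reverse)
        starts = [i for i in range(len(template) - fl + 1) if template[i : i + fl] == m.forward]
        ends = [i + rl for i in range(len(template) - rl + 1) if template[i : i + rl] == rc]
        brute = sorted((i, j) for i in starts for j in ends if 0 < j - i <= 3_000)
        assert amps == brute
        assert len(amps) == 2

    def test_reverse_oriented_template(self):
        m = _marker()
        template = "T" * 40 + revcomp(amplifiable(m)) + "T" * 40
        assert insilico_pcr(template, m) != []
        assert insilico_pcr(template, m, both_orientations=False) == []

    def test_mismatch_tolerance(self):
        m = _marker()
        body = amplifiable(m)
        mutated = "C" + body[1:]  # one mismatch in the forward site
        assert insilico_pcr(mutated, m, max_mismatch=0, both_orientations=False) == []
        assert insilico_pcr(mutated, m, max_mismatch=1, both_orientations=False) != []

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr("", _marker())


def _grid_library(positive_addresses, marker, layout=(2, 2, 2)):
    """Library filling the full grid; clones at positive_addresses amplify."""
    clones = []
    for i, addr in enumerate(itertools.product(*(range(n) for n in layout))):
        seq = amplifiable(marker) if addr in positive_addresses else "T" * 400
        clones.append(_clone(f"c{i}", addr, seq))
    return _library(clones, layout)


class TestScreenAndDeconvolve:
    def test_no_amplifying_clone_gives_all_negative(self):
        m = _marker()
        lib = _grid_library(set(), m)
        design = build_3d_pools(lib)
        signals = screen_pools(design, lib, [m])
        assert not signals.entries[m.marker_id].any()

    def test_single_positive_clone_lights_three_pools(self):
        m = _marker()
        lib = _grid_library({(1, 0, 1)}, m)
        design = build_3d_pools(lib)
        signals = screen_pools(design, lib, [m])
        positives = signals.positives(m.marker_id)
        assert positives == {"P1", "R0", "C1"}
        assert deconvolve(signals, design, m.marker_id) == {
            c.clone_id for c in lib.clones if c.address == (1, 0, 1)
        }

    def test_ghost_candidates_removed_by_confirmation(self):
        m = _marker()
        # two clones on a diagonal produce two ghost addresses
        lib = _grid_library({(0, 0, 0), (1, 1, 1)}, m)
        design = build_3d_pools(lib)
        signals = screen_pools(design, lib, [m])
        candidates = deconvolve(signals, design, m.marker_id)
        assert len(candidates) == 8  # 2 plates x 2 rows x 2 cols all positive
        confirmed = confirm_candidates(candidates, m, lib)
        truth = {c.clone_id for c in lib.clones if c.address in {(0, 0, 0), (1, 1, 1)}}
        assert confirmed == truth

    def test_all_negative_axis_gives_empty_candidates(self):
        m = _marker()
        lib = _grid_library(set(), m)
        design = build_3d_pools(lib)
        signals = screen_pools(design, lib, [m])
        assert deconvolve(signals, design, m.marker_id) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_deconvolution_matches_cartesian_oracle(self, seed):
        """Candidate set equals positive-plate x positive-row x positive-col
        intersected with occupied addresses, on random partial grids."""
        rng = random.Random(seed)
        m = _marker()
        layout = (rng.randint(1, 3), rng.randint(1, 3), rng.randint(1, 3))
        all_addrs = list(itertools.product(*(range(n) for n in layout)))
        occupied = rng.sample(all_addrs, k=rng.randint(1, len(all_addrs)))
        amplifying = set(rng.sample(occupied, k=rng.randint(0, len(occupied))))
        clones = []
        for i, addr in enumerate(occupied):
            seq = amplifiable(m) if addr in amplifying else "T" * 400
            clones.append(_clone(f"c{i}", addr, seq))
        lib = _library(clones, layout)
        design = build_3d_pools(lib)
        signals = screen_pools(design, lib, [m])
        pos = signals.positives(m.marker_id)
        plates = {int(p[1:]) for p in pos if p.startswith("P")}
        rows = {int(p[1:]) for p in pos if p.startswith("R")}
        cols = {int(p[1:]) for p in pos if p.startswith("C")}
        oracle = {
            c.clone_id
            for c in clones
            if c.address[0] in plates and c.address[1] in rows and c.address[2] in cols
        }
        assert deconvolve(signals, design, m.marker_id) == oracle
        assert confirm_candidates(deconvolve(signals, design, m.marker_id), m, lib) == {
            c.clone_id for c in clones if c.address in amplifying
        }


class TestSelectBacs:
    def test_double_positive_rule(self):
        confirmed = {"m1": {"a", "b"}, "m2": {"b"}, "m3": {"c"}}
        assert select_bacs(confirmed, min_markers=2) == {"b"}

    def test_empty(self):
        assert select_bacs({}, 2) == set()

    def test_monotone_in_confirmed_markers(self):
        rng = random.Random(0)
        clones = [f"c{i}" for i in range(10)]
        confirmed = {f"m{j}": set(rng.sample(clones, 4)) for j in range(5)}
        base = select_bacs(confirmed, 2)
        confirmed["m_new"] = set(rng.sample(clones, 5))
        assert select_bacs(confirmed, 2) >= base


def _brute_force_min_pools(clones, marker_map, capacity):
    conflicts = {
        (a, b)
        for i, a in enumerate(clones)
        for b in clones[i + 1 :]
        if set(marker_map.get(a, ())) & set(marker_map.get(b, ()))
    }

    def feasible(k):
        assignment = {}

        def backtrack(idx):
            if idx == len(clones):
                return True
            c = clones[idx]
            used = {assignment[x] for x in assignment}
            for pool in range(min(k, len(used) + 1)):
                members = [x for x in assignment if assignment[x] == pool]
                if len(members) >= capacity:
                    continue
                if any((min(c, x), max(c, x)) in conflicts for x in members):
                    continue
                assignment[c] = pool
                if backtrack(idx + 1):
                    return True
                del assignment[c]
            return False

        return backtrack(0)

    k = 1
    while not feasible(k):
        k += 1
    return k


class TestPlanSequencingPools:
    def test_conflict_free_fits_one_pool(self):
        clones = [f"c{i}" for i in range(8)]
        marker_map = {c: {f"m{i}"} for i, c in enumerate(clones)}
        plan = plan_sequencing_pools(clones, marker_map, capacity=8)
        assert plan.n_pools == 1
        assert verify_plan(plan, marker_map) == []

    def test_triangle_needs_three_pools(self):
        marker_map = {"a": {"m1", "m2"}, "b": {"m2", "m3"}, "c": {"m3", "m1"}}
        plan = plan_sequencing_pools(["a", "b", "c"], marker_map, capacity=8)
        assert plan.n_pools == 3

    def test_capacity_forces_ceiling(self):
        clones = [f"c{i}" for i in range(20)]
        marker_map = {c: {f"m{i}"} for i, c in enumerate(clones)}
        plan = plan_sequencing_pools(clones, marker_map, capacity=8)
        assert plan.n_pools == 3  # ceil(20 / 8)

    @pytest.mark.parametrize("seed", range(10))
    def test_near_optimal_on_random_instances(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 10)
        clones = [f"c{i}" for i in range(n)]
        markers = [f"m{j}" for j in range(rng.randint(2, 6))]
        marker_map = {c: set(rng.sample(markers, rng.randint(1, 2))) for c in clones}
        capacity = rng.randint(2, 5)
        plan = plan_sequencing_pools(clones, marker_map, capacity)
        assert verify_plan(plan, marker_map) == []
        optimum = _brute_force_min_pools(clones, marker_map, capacity)
        assert plan.n_pools <= optimum + 1


class TestCloneMarkerMatrix:
    def test_matrix_matches_per_clone_pcr(self):
        m1, m2 = _marker(mid="m1"), _marker("GTGTACACGTGTACACGTGT", "CACGTGTACACGTGTACACG", "m2", "g2")
        clones = [
            _clone("c0", (0, 0, 0), amplifiable(m1)),
            _clone("c1", (0, 0, 1), amplifiable(m1) + amplifiable(m2)),
            _clone("c2", (0, 1, 0), "T" * 500),
        ]
        cm = clone_marker_matrix(clones, [m1, m2])
        expected = pd.DataFrame(
            [[True, False], [True, True], [False, False]],
            index=["c0", "c1", "c2"],
            columns=["m1", "m2"],
        )
        assert cm.equals(expected)
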