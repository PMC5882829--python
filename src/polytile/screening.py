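"""3D-pool BAC screening, deconvolution, selection, and pool planning.

A clone library laid out as plates x rows x columns is screened one pool
per axis value: a clone at address (p, r, c) contributes to plate-pool p,
row-pool r and column-pool c.  A marker's positive pools locate candidate
clones by intersection; per-clone confirmation PCR resolves the ghost
addresses that 3D pooling inevitably produces when several clones amplify
the same marker.  Selected clones (>= 2 distinct markers — the
double-positive rule that guards against pseudogenes and stray gene
fragments) are then packed into sequencing pools so that no two clones
sharing a marker end up in the same pool, which keeps homeologous copies
of a gene out of a single assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import encode, revcomp, scan_mismatch_positions
from .markers import MarkerPair
from .simulate import BacClone, BacLibrary

__all__ = [
    "PoolDesign",
    "PoolSignalMatrix",
    "SequencingPoolPlan",
    "build_3d_pools",
    "insilico_pcr",
    "clone_marker_matrix",
    "screen_pools",
    "deconvolve",
    "confirm_candidates",
    "select_bacs",
    "plan_sequencing_pools",
    "verify_plan",
]


@dataclass
class PoolDesign:
    pools: dict[str, set[str]]  # pool_id -> clone ids
    axes: tuple[list[str], list[str], list[str]]  # plate-, row-, column-pool ids
    clone_pools: dict[str, tuple[str, str, str]]  # clone -> its three pools

    def all_clones(self) -> set[str]:
        return set(self.clone_pools)


@dataclass
class PoolSignalMatrix:
    """Boolean pool x marker PCR outcome matrix."""

    entries: pd.DataFrame  # index: pool_id, columns: marker_id, dtype bool

    def positives(self, marker_id: str) -> set[str]:
        col = self.entries[marker_id]
        return set(col.index[col])


@dataclass
class SequencingPoolPlan:
    assignment: dict[str, int]  # clone_id -> pool index
    capacity: int = 8

    @property
    def n_pools(self) -> int:
        return 1 + max(self.assignment.values()) if self.assignment else 0

    def pools(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_pools)]
        for clone, idx in sorted(self.assignment.items()):
            out[idx].append(clone)
        return out


# ---------------------------------------------------------------------------
# Pool construction


def build_3d_pools(library: BacLibrary) -> PoolDesign:
    """One pool per plate, per row index and per column index; every clone
    lands in exactly three pools, one per axis."""
    n_plates, n_rows, n_cols = library.layout
    plate_ids = [f"P{p}" for p in range(n_plates)]
    row_ids = [f"R{r}" for r in range(n_rows)]
    col_ids = [f"C{c}" for c in range(n_cols)]
    pools: dict[str, set[str]] = {pid: set() for pid in plate_ids + row_ids + col_ids}
    clone_pools: dict[str, tuple[str, str, str]] = {}
    for clone in library.clones:
        p, r, c = clone.address
        trio = (f"P{p}", f"R{r}", f"C{c}")
        for pid in trio:
            pools[pid].add(clone.clone_id)
        clone_pools[clone.clone_id] = trio
    return PoolDesign(pools, (plate_ids, row_ids, col_ids), clone_pools)


# ---------------------------------------------------------------------------
# In-silico PCR


def _paired_sites(starts: np.ndarray, ends: np.ndarray, max_amplicon: int) -> list[tuple[int, int]]:
    """All (i, j) with a left-primer start i and right-primer end j such
    that 0 < j - i <= max_amplicon."""
    out = []
    ends_sorted = np.sort(ends)
    for i in starts:
        lo = np.searchsorted(ends_sorted, i + 1)
        hi = np.searchsorted(ends_sorted, i + max_amplicon, side="right")
        for j in ends_sorted[lo:hi]:
            out.append((int(i), int(j)))
    return out


def insilico_pcr(
    template: str,
    marker: MarkerPair,
    max_amplicon: int = 3_000,
    max_mismatch: int = 0,
    both_orientations: bool = True,
) -> list[tuple[int, int]]:
    """Amplicon intervals the primer pair would produce on the template.

    An amplicon is a forward-primer site followed within ``max_amplicon``
    by a reverse-complemented reverse-primer site, each matching with at
    most ``max_mismatch`` mismatches.  With ``both_orientations`` the
    reverse-oriented template is amplified too (as in a real PCR on
    double-stranded DNA); intervals are always reported on the given
    template's coordinates.
    """
    if not template:
        raise ValueError("insilico_pcr requires a non-empty template")
    t = encode(template)
    amps: list[tuple[int, int]] = []
    fwd = encode(marker.forward)
    rev_rc = encode(revcomp(marker.reverse))
    starts = scan_mismatch_positions(t, fwd, max_mismatch)
    if len(starts):
        ends = scan_mismatch_positions(t, rev_rc, max_mismatch) + len(rev_rc)
        amps += _paired_sites(starts, ends, max_amplicon)
    if both_orientations:
        rev = encode(marker.reverse)
        fwd_rc = encode(revcomp(marker.forward))
        starts2 = scan_mismatch_positions(t, rev, max_mismatch)
        if len(starts2):
            ends2 = scan_mismatch_positions(t, fwd_rc, max_mismatch) + len(fwd_rc)
            amps += _paired_sites(starts2, ends2, max_amplicon)
    return sorted(set(amps))


# ---------------------------------------------------------------------------
# Screening and deconvolution


def clone_marker_matrix(
    clones: Sequence[BacClone],
    markers: Sequence[MarkerPair],
    max_amplicon: int = 3_000,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Boolean clone x marker amplification matrix (the per-clone PCR truth
    the pool signals derive from)."""
    data = np.zeros((len(clones), len(markers)), dtype=bool)
    for i, clone in enumerate(clones):
        for j, marker in enumerate(markers):
            data[i, j] = bool(
                insilico_pcr(clone.insert_sequence, marker, max_amplicon, max_mismatch)
            )
    return pd.DataFrame(data, index=[c.clone_id for c in clones], columns=[m.marker_id for m in markers])


def screen_pools(
    design: PoolDesign,
    library: BacLibrary,
    markers: Sequence[MarkerPair],
    max_amplicon: int = 3_000,
    max_mismatch: int = 0,
    clone_matrix: pd.DataFrame | None = None,
) -> PoolSignalMatrix:
    """Pool x marker signals: a pool is positive for a marker iff any of its
    clones yields at least one amplicon."""
    cm = clone_matrix if clone_matrix is not None else clone_marker_matrix(
        library.clones, markers, max_amplicon, max_mismatch
    )
    pool_ids = [pid for axis in design.axes for pid in axis]
    data = np.zeros((len(pool_ids), cm.shape[1]), dtype=bool)
    for k, pid in enumerate(pool_ids):
        members = sorted(design.pools[pid])
        if members:
            data[k] = cm.loc[members].to_numpy().any(axis=0)
    return PoolSignalMatrix(pd.DataFrame(data, index=pool_ids, columns=cm.columns))


def deconvolve(signals: PoolSignalMatrix, design: PoolDesign, marker_id: str) -> set[str]:
    """Clones whose plate-, row- and column-pools are all positive for the
    marker (the Cartesian product of positive axis pools intersected with
    occupied addresses)."""
    positive = signals.positives(marker_id)
    return {
        clone
        for clone, trio in design.clone_pools.items()
        if all(pid in positive for pid in trio)
    }


def confirm_candidates(
    candidates: Iterable[str],
    marker: MarkerPair,
    library: BacLibrary,
    max_amplicon: int = 3_000,
    max_mismatch: int = 0,
) -> set[str]:
    """Per-clone confirmation PCR: keep candidates whose own insert yields
    an amplicon, removing ghost addresses."""
    by_id = {c.clone_id: c for c in library.clones}
    confirmed = set()
    for clone_id in candidates:
        clone = by_id[clone_id]
        if insilico_pcr(clone.insert_sequence, marker, max_amplicon, max_mismatch):
            confirmed.add(clone_id)
    return confirmed


def select_bacs(confirmed: Mapping[str, Iterable[str]], min_markers: int = 2) -> set[str]:
    """Clones confirmed for at least ``min_markers`` distinct markers
    (double-positive selection)."""
    counts: dict[str, int] = {}
    for marker_id, clones in confirmed.items():
        for clone_id in set(clones):
            counts[clone_id] = counts.get(clone_id, 0) + 1
    return {clone_id for clone_id, n in counts.items() if n >= min_markers}


# ---------------------------------------------------------------------------
# Sequencing-pool planning


def plan_sequencing_pools(
    selected: Iterable[str],
    marker_map: Mapping[str, Iterable[str]],
    capacity: int = 8,
) -> SequencingPoolPlan:
    """Pack selected clones into sequencing pools of at most ``capacity``
    such that no two clones sharing a marker share a pool.

    Clones sharing a gene marker are potential homeologous copies; keeping
    them in separate pools avoids chimeric co-assembly.  Uses greedy
    largest-degree-first coloring with first-fit pool choice — not provably
    minimal, but within one pool of the optimum on small instances.
    """
    clones = sorted(set(selected))
    msets = {c: frozenset(marker_map.get(c, ())) for c in clones}
    degree = {
        c: sum(1 for o in clones if o != c and msets[c] & msets[o]) for c in clones
    }
    order = sorted(clones, key=lambda c: (-degree[c], c))
    pools: list[list[str]] = []
    assignment: dict[str, int] = {}
    for c in order:
        placed = False
        for idx, members in enumerate(pools):
            if len(members) >= capacity:
                continue
            if any(msets[c] & msets[m] for m in members):
                continue
            members.append(c)
            assignment[c] = idx
            placed = True
            break
        if not placed:
            pools.append([c])
            assignment[c] = len(pools) - 1
    return SequencingPoolPlan(assignment, capacity)


def verify_plan(
    plan: SequencingPoolPlan, marker_map: Mapping[str, Iterable[str]]
) -> list[str]:
    """Independent constraint check; returns violations (empty = valid)."""
    problems = []
    for idx, members in enumerate(plan.pools()):
        if len(members) > plan.capacity:
            problems.append(f"pool {idx} holds {len(members)} > capacity {plan.capacity}")
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                shared = set(marker_map.get(a, ())) & set(marker_map.get(b, ()))
                if shared:
                    problems.append(f"pool {idx}: {a} and {b} share markers {sorted(shared)}")
    return problems
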