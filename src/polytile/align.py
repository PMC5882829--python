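"""Seed-and-extend local alignment with an exact dynamic-programming core.

The aligner stands in for a BLASTn-style search: 11-mer seeds locate
candidate windows on large subjects, and an affine-gap Smith-Waterman
(Gotoh) kernel computes the exact local alignment inside each window.
For small inputs (both sequences <= 2 kb) the full DP is run directly, so
the seeded path can never miss an alignment there.

Scoring convention: match +1, mismatch -2, and a gap of length L costs
gap_open + (L-1) * gap_extend (first gapped column pays the open score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .genome import CoordinateInterval

__all__ = [
    "Scoring",
    "AlignmentHit",
    "SubjectIndex",
    "local_align",
    "find_loci",
    "revcomp",
    "encode",
    "scan_mismatch_positions",
]

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# op codes in traceback arrays
OP_MATCH, OP_MISMATCH, OP_INS, OP_DEL = 0, 1, 2, 3

MAX_FULL_DP_CELLS = 4_500_000  # both sequences ~2 kb


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit base encoding; anything outside ACGT becomes code 4 (never matches)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class AlignmentHit:
    """Best local alignment between a query and a subject.

    ``identity`` is computed over aligned columns excluding gaps.  ``e_like``
    is a simplified significance surrogate m*n*2**(-score): monotone in
    score and adequate for thresholding, but not Karlin-Altschul calibrated.
    """

    query_id: str
    subject_id: str
    score: int
    identity: float
    query_span: CoordinateInterval
    subject_span: CoordinateInterval
    e_like: float
    strand: str = "+"
    n_match: int = 0
    n_mismatch: int = 0
    ops: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8), repr=False)

    @property
    def query_coverage_of(self) -> float:
        return len(self.query_span)

    def identity_in_query_range(self, q_start: int, q_end: int) -> tuple[float, int]:
        """(identity, aligned columns) over the part of the alignment whose
        query coordinate falls in [q_start, q_end)."""
        qpos = self.query_span.start
        n_m = n_x = 0
        for op in self.ops:
            consumed_q = op in (OP_MATCH, OP_MISMATCH, OP_DEL)
            if consumed_q and q_start <= qpos < q_end:
                if op == OP_MATCH:
                    n_m += 1
                elif op == OP_MISMATCH:
                    n_x += 1
            if consumed_q:
                qpos += 1
        cols = n_m + n_x
        return (n_m / cols if cols else 0.0), cols

    def query_covered_fraction(self, query_length: int) -> float:
        return len(self.query_span) / query_length


@njit(cache=True)
def _sw_kernel(q, s, match, mismatch, gap_open, gap_extend):
    """Affine-gap local alignment with traceback.

    Returns (score, q_start, q_end, s_start, s_end, ops, n_ops) where ops is
    a reversed op-code array (codes: 0 match, 1 mismatch, 2 insertion in
    subject, 3 deletion from subject).
    """
    n, m = len(q), len(s)
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap consuming subject (horizontal)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap consuming query (vertical)
    best = 0
    bi = bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = bi, bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 or j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            sub = match if (i > 0 and j > 0 and q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + sub:
                ops[k] = 0 if sub == match else 1
                k += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 2
            k += 1
            if E[i, j] == E[i, j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = 0
        else:
            ops[k] = 3
            k += 1
            if F[i, j] == F[i - 1, j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = 0
    return best, i, bi, j, bj, ops, k


@njit(cache=True)
def scan_mismatch_positions(template, primer, max_mm):
    """All start positions where primer matches template with <= max_mm
    mismatches (codes >= 4 never match)."""
    n, L = len(template), len(primer)
    out = np.empty(max(n - L + 1, 0), dtype=np.int64)
    cnt = 0
    for i in range(n - L + 1):
        mm = 0
        for k in range(L):
            t = template[i + k]
            p = primer[k]
            if t != p or t >= 4:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            out[cnt] = i
            cnt += 1
    return out[:cnt]


def _hit_from_kernel(res, q_len, s_len, query_id, subject_id, chrom_q, chrom_s, s_offset, scoring):
    score, qs, qe, ss, se, ops_rev, k = res
    if score <= 0 or qe <= qs or se <= ss:
        return None
    ops = ops_rev[:k][::-1].copy()
    n_match = int(np.sum(ops == OP_MATCH))
    n_mismatch = int(np.sum(ops == OP_MISMATCH))
    cols = n_match + n_mismatch
    identity = n_match / cols if cols else 0.0
    exponent = -int(score)
    e_like = 0.0 if score > 200 else float(q_len) * float(s_len) * math.pow(2.0, exponent)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=int(score),
        identity=identity,
        query_span=CoordinateInterval(chrom_q, qs, qe),
        subject_span=CoordinateInterval(chrom_s, s_offset + ss, s_offset + se),
        e_like=e_like,
        n_match=n_match,
        n_mismatch=n_mismatch,
        ops=ops,
    )


def _full_dp(q_arr, s_arr, q_len, s_len, query_id, subject_id, s_offset, scoring):
    res = _sw_kernel(
        q_arr, s_arr, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    return _hit_from_kernel(res, q_len, s_len, query_id, subject_id, query_id, subject_id, s_offset, scoring)


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; windows containing non-ACGT get -1."""
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    bad = np.zeros(n - k + 1, dtype=bool)
    a = arr.astype(np.int64)
    for off in range(k):
        window = a[off : off + n - k + 1]
        codes = (codes << 2) | (window & 3)
        bad |= window >= 4
    codes[bad] = -1
    return codes


class SubjectIndex:
    """Sorted k-mer index over a subject sequence (both strands), reusable
    across many queries against the same subject."""

    def __init__(self, subject: str, k: int = 11):
        self.subject = subject
        self.k = k
        self._strands: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for strand, seq in (("+", subject), ("-", revcomp(subject))):
            arr = encode(seq)
            sc = _kmer_codes(arr, k)
            order = np.argsort(sc, kind="stable").astype(np.int64)
            self._strands[strand] = (arr, sc[order], order)

    def arr(self, strand: str) -> np.ndarray:
        return self._strands[strand][0]

    def sorted_codes(self, strand: str) -> tuple[np.ndarray, np.ndarray]:
        _, sc_sorted, order = self._strands[strand]
        return sc_sorted, order


def _seed_windows(
    q_arr: np.ndarray,
    s_arr: np.ndarray,
    k: int = 11,
    band: int = 60,
    pad: int = 200,
    min_seeds: int = 1,
    sorted_index: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Candidate subject windows from exact k-mer seed matches, clustered by
    alignment diagonal and subject position.  Clusters with fewer than
    ``min_seeds`` matches are discarded as chance collisions."""
    qc = _kmer_codes(q_arr, k)
    if len(qc) == 0:
        return []
    if sorted_index is not None:
        sc_sorted, order = sorted_index
    else:
        sc = _kmer_codes(s_arr, k)
        if len(sc) == 0:
            return []
        order = np.argsort(sc, kind="stable")
        sc_sorted = sc[order]
    if len(sc_sorted) == 0:
        return []
    qpos_list = []
    spos_list = []
    valid = qc >= 0
    lo = np.searchsorted(sc_sorted, qc)
    hi = np.searchsorted(sc_sorted, qc, side="right")
    for qi in np.nonzero(valid & (hi > lo))[0]:
        sp = order[lo[qi] : hi[qi]]
        qpos_list.append(np.full(len(sp), qi, dtype=np.int64))
        spos_list.append(sp.astype(np.int64))
    if not qpos_list:
        return []
    qpos = np.concatenate(qpos_list)
    spos = np.concatenate(spos_list)
    diag = spos - qpos
    order = np.lexsort((spos, diag))
    qpos, spos, diag = qpos[order], spos[order], diag[order]
    qlen = len(q_arr)
    windows = []
    start = 0
    for idx in range(1, len(diag) + 1):
        new_cluster = idx == len(diag) or diag[idx] - diag[idx - 1] > band or (
            diag[idx] == diag[idx - 1] and spos[idx] - spos[idx - 1] > qlen + pad
        )
        if new_cluster:
            cl_s = spos[start:idx]
            cl_q = qpos[start:idx]
            if idx - start >= min_seeds:
                w_start = max(0, int(cl_s.min() - cl_q.max()) - pad)
                w_end = min(len(s_arr), int(cl_s.max() + (qlen - cl_q.min())) + pad)
                windows.append((w_start, w_end, idx - start))
            start = idx
    # merge overlapping windows
    windows.sort()
    merged = []
    for w in windows:
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]), merged[-1][2] + w[2])
        else:
            merged.append(list(w))
            merged[-1] = tuple(merged[-1])
    return merged


def local_align(
    query: str,
    subject: str,
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    subject_id: str = "subject",
    k: int = 11,
) -> Optional[AlignmentHit]:
    """Best positive-scoring local alignment, or None if none exists."""
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    q_arr, s_arr = encode(query), encode(subject)
    if len(query) * len(subject) <= MAX_FULL_DP_CELLS:
        return _full_dp(q_arr, s_arr, len(query), len(subject), query_id, subject_id, 0, scoring)
    best: Optional[AlignmentHit] = None
    for w_start, w_end, _ in _seed_windows(q_arr, s_arr, k=k):
        hit = _full_dp(
            q_arr, s_arr[w_start:w_end], len(query), len(subject), query_id, subject_id, w_start, scoring
        )
        if hit and (best is None or (hit.score, hit.identity) > (best.score, best.identity)):
            best = hit
    return best


def find_loci(
    query: str,
    subject: "str | SubjectIndex",
    min_identity: float = 0.8,
    min_query_cov: float = 0.5,
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    subject_id: str = "subject",
    both_strands: bool = True,
    k: int = 11,
    min_seeds: int = 3,
) -> list[AlignmentHit]:
    """All distinct subject loci where the query aligns above thresholds.

    Each seed-cluster window yields at most one hit; hits whose subject
    intervals overlap are deduplicated keeping the higher-scoring one.
    Minus-strand hits carry strand '-' with plus-strand subject coordinates.
    Pass a prebuilt :class:`SubjectIndex` when scanning many queries
    against the same subject.
    """
    index = subject if isinstance(subject, SubjectIndex) else None
    subject_seq = index.subject if index is not None else subject
    if not query or not subject_seq:
        return []
    if index is not None and index.k != k:
        raise ValueError("SubjectIndex built with a different k")
    q_arr = encode(query)
    hits: list[AlignmentHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        if index is not None:
            s_arr = index.arr(strand)
        else:
            subj = subject_seq if strand == "+" else revcomp(subject_seq)
            s_arr = encode(subj)
        # exhaustive DP only when the subject is barely larger than the
        # query; otherwise seed.  (A single full-subject DP could only ever
        # report one locus anyway.)
        if len(subject_seq) <= 4 * len(query) + 800 and len(query) * len(subject_seq) <= MAX_FULL_DP_CELLS:
            windows = [(0, len(s_arr), 0)]
        else:
            sorted_index = index.sorted_codes(strand) if index is not None else None
            windows = _seed_windows(q_arr, s_arr, k=k, min_seeds=min_seeds, sorted_index=sorted_index)
        for w_start, w_end, _ in windows:
            # iterative mask-and-realign so one window can yield several
            # loci (e.g. adjacent tandem copies)
            window = s_arr[w_start:w_end].copy()
            for _round in range(6):
                hit = _full_dp(
                    q_arr, window, len(query), len(subject_seq), query_id, subject_id, w_start, scoring
                )
                if hit is None:
                    break
                if hit.identity < min_identity or hit.query_covered_fraction(len(query)) < min_query_cov:
                    break
                ss, se = hit.subject_span.start, hit.subject_span.end
                window[ss - w_start : se - w_start] = 4
                if strand == "-":
                    hit.subject_span = CoordinateInterval(
                        subject_id, len(subject_seq) - se, len(subject_seq) - ss
                    )
                    hit.strand = "-"
                hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.subject_span.start))
    kept: list[AlignmentHit] = []
    for h in hits:
        if any(h.subject_span.overlaps(kh.subject_span) for kh in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.subject_span.start)
    return kept
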