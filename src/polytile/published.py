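"""Published per-pool sequencing/assembly statistics used as fixtures.

These are the nine sequencing-pool rows reported for the sugarcane
SP80-3280 BAC-pool study that this tool's workflow models (PacBio
sequencing of 68 clones in nine pools, Celera assembly).  They exercise
the aggregate arithmetic exactly as printed.  Contig sizes are treated as
base pairs throughout (the published table's "kb" unit label is internally
inconsistent).
"""

from __future__ import annotations

from .qc import PoolStats

__all__ = ["SUGARCANE_POOL_ROWS", "SUGARCANE_CONTIG_FILTER"]

# pool_id, n_bacs, trimmed_reads, host_pct, n_contigs, longest, smallest,
# total_length, n50, gc_pct
_ROWS = [
    ("Pool 01", 4, 178_758, 5.0, 16, 143_471, 9_202, 582_340, 62_347, 43.77),
    ("Pool 02", 8, 202_770, 7.0, 17, 134_154, 8_615, 1_034_115, 109_126, 45.08),
    ("Pool 03", 8, 139_394, 13.0, 25, 142_211, 8_101, 800_349, 54_726, 45.45),
    ("Pool 04", 8, 206_601, 8.0, 27, 122_448, 9_303, 882_224, 41_554, 44.06),
    ("Pool 05", 8, 189_764, 9.6, 16, 175_157, 8_050, 1_186_577, 132_868, 45.28),
    ("Pool 06", 8, 237_520, 9.0, 21, 168_704, 8_289, 920_150, 86_198, 44.75),
    ("Pool 07", 8, 143_827, 6.8, 19, 164_848, 10_668, 1_140_957, 128_641, 45.41),
    ("Pool 08", 8, 186_873, 7.4, 19, 143_661, 10_202, 1_129_862, 108_955, 44.41),
    ("Pool 09", 8, 174_835, 8.4, 20, 187_285, 10_664, 1_261_846, 99_030, 44.43),
]

SUGARCANE_POOL_ROWS: list[PoolStats] = [PoolStats(*row) for row in _ROWS]

# Of the 180 assembled contigs, 112 were shorter than 50 kb and/or had low
# assembly coverage and were excluded from the synteny analysis.
SUGARCANE_CONTIG_FILTER = {"total": 180, "removed": 112}
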