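# Methods

`polytile` models and tests a strategy for reconstructing a complex
polyploid genomic region — the kind found in sugarcane, with 8–12
homeologous copies of every locus and roughly half the DNA in repeats —
using a closely related diploid genome (sorghum-like) as a syntenic
scaffold. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## The reconstruction strategy

The pipeline chains seven stages:

1. **Region model.** A reference region is a sequence plus an ordered list
   of gene models (0-based, half-open coordinates throughout; conversion
   happens only at the GFF3 boundary). The index of each gene along the
   region (0..n−1) is the coordinate system for all downstream synteny
   work. Region extraction keeps any gene overlapping the target window by
   ≥1 bp; boundary genes are not silently dropped.
2. **Marker design.** Each reference gene's spliced CDS is matched to the
   target-genome transcriptome by local alignment; the best transcript hit
   (score, then identity, then lexicographic id — order-invariant) is
   accepted below a significance surrogate `e_like = m·n·2^(−score)` with
   cutoff 1e−10. Within the aligned span, exons ≥140 bp at per-exon
   identity ≥0.95 are candidate templates; a primer pair (18–24 nt, GC
   40–60%, ΔTm ≤ 3 °C by the GC-fraction formula Tm = 81.5 + 0.41·GC% −
   675/len, amplicon 100–1000 bp, both primers unique in the
   transcriptome) is designed inside a single exon so the amplicon spans
   no intron and can amplify every homeologous copy. One marker per gene.
3. **3D-pool screening.** The clone library lives on a plates × rows ×
   columns grid; DNA is pooled once per axis value, so a clone sits in
   exactly three pools. A marker's positive pools give candidate addresses
   by intersection (plate × row × column of positives, restricted to
   occupied wells); because several true positives create ghost
   intersections, every candidate is confirmed by a per-clone PCR. PCR is
   simulated exactly: a primer site matches with at most `max_mismatch`
   mismatches, amplicons are capped at 3 kb, and both template
   orientations amplify (PCR acts on double-stranded DNA).
4. **Double-positive selection.** A clone is carried forward only when it
   confirms for ≥2 distinct gene markers. This guards against pseudogenes,
   stray gene fragments and repeat-borne false positives.
5. **Sequencing-pool planning.** Clones sharing any marker are potential
   homeologous copies of the same gene and must not be co-assembled:
   the conflict graph (edge = shared marker) is colored greedily
   (largest degree first, first-fit pool, capacity 8). Greedy coloring is
   not provably minimal — the exact capacity-constrained problem is
   NP-hard — but on random instances ≤12 clones it matches the
   backtracking optimum or exceeds it by one pool (property-tested).
6. **Pool QC.** Reads are screened against the cloning vector (exact
   20-bp seeds extended to maximal runs; terminal matches trimmed,
   interior matches masked) and the host genome (21-mer screen, a read is
   host when ≥50% of its k-mers are host-derived), then length-filtered at
   500 bp. Per-pool statistics mirror the conventional pool-assembly
   table: read counts, host %, contig count, extreme lengths, total
   length, N50 (largest L with contigs ≥L summing to ≥ half the total; an
   independent definition oracle is property-tested), GC% excluding N.
   Contigs shorter than 50 kb (strictly) or with coverage below 0.25× the
   pool median are excluded from synteny analysis. The 0.25× median rule
   is this package's operationalization of "low coverage": it is
   scale-free and robust to per-pool depth differences; the fraction is
   configurable.
7. **Synteny reconstruction.** Each reference gene is located on a contig
   by exon-wise alignment: every exon is aligned separately (an intron on
   the contig then costs nothing) and exon hits are chained into gene loci
   — exon indices must increase along the plus strand (decrease along
   minus) with inter-exon gaps ≤5 kb; a repeated exon index starts a new
   locus, which keeps adjacent tandem copies separate. A locus is reported
   at ≥50% chained CDS coverage and ≥0.8 weighted identity. From the
   per-contig gene hits follow: collinearity (monotone gene order after
   collapsing tandem repeats), tandem duplications (two adjacent
   same-strand hits of one gene), syntenic blocks (maximal runs of
   consecutively covered reference gene indices) with their gaps, and a
   minimal tiling path per block via greedy interval cover (leftmost
   uncovered gene → furthest-reaching clone; ties to the longer sequence,
   then smaller id). Greedy is optimal for interval cover; the property
   suite confirms it against exhaustive subset enumeration.

### Homeolog discrimination

Two overlapping contigs are compared over the span of their shared genes.
The decision rule mirrors the two physical situations:

* **Same homeolog** — the spans align essentially end to end:
  aligned fraction ≥0.95 of alignment columns at identity ≥0.99 over
  aligned columns. Overlapping clones from one homeolog are near-identical
  copies of the same molecule, so these thresholds are deliberately strict.
* **Different homeologs** — the shared genes are collinear and each aligns
  well (identity ≥0.8), but the intergenic DNA between them does not
  (aligned fraction of the concatenated inter-gene gaps <0.5): homeologs
  conserve genes and gene order while their intergenic space diverges and
  accumulates independent repeat insertions.
* Anything overlapping that fits neither template is called *different*
  with a low-confidence flag; disjoint mapped ranges are *unrelated*.

Long-span alignments use edlib (bit-parallel global edit-distance
alignment); identity is computed over aligned columns (`=`/`X`), aligned
fraction over all columns including gaps. Clusters of "same" calls are
connected components; a "different" call inside a component is reported as
a warning and "same" wins (sequence-level identity is stronger evidence
than one failed pairwise test).

## The aligner

The core aligner is an affine-gap Smith–Waterman (Gotoh) with match +1,
mismatch −2, gap open −5, gap extend −2; a gap of length L costs
`open + (L−1)·extend`. For large subjects, exact 11-mer seeds are clustered
by alignment diagonal (band 60) into candidate windows and the DP runs per
window; clusters with fewer than 3 seeds are discarded as chance
collisions (at the identities where a hit can matter, dozens to hundreds
of seeds survive). Each window is re-aligned iteratively with the previous
hit masked (≤6 rounds), so several loci inside one window — adjacent
tandem copies in particular — are all found. For inputs up to ~2 kb the
full DP runs directly, and the property suite checks exact score equality
against an independent dynamic-programming implementation on random pairs,
including gapped ones. `e_like` is not Karlin–Altschul calibrated; it is a
monotone-in-score thresholding surrogate, which is all the best-hit step
needs.

## The simulator

The generator emulates the statistical structure of the study system; its
defaults are the study conditions and are not tuned per run:

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_genes` / `region_length_bp` | 61 / 687 kb | reference gene complement and size |
| `ploidy` | 10 | homeologous copies (8–12 plausible range) |
| `genic_divergence` | 0.02 | substitutions/bp in genes, homeolog vs reference |
| `intergenic_divergence` | 0.10 | substitutions/bp between genes, plus indels at 10% of that rate (geometric, mean 3 bp) |
| `repeat_fraction_target` | 0.51 | fraction of each homeolog covered by TE insertions |
| `te_class_mix` | 41:8:2 | LTR : DNA : non-LTR insertion counts |
| `ltr_family_mix` | 58:42 | Gypsy : Copia within LTR |
| `te_length_range` | 146–11,800 bp | element sizes (Stowaway to full-length LTR) |
| `n_tandem_dup_genes` | 6 | genes given an adjacent duplicate on one random homeolog |
| `transcript_detect_count` | 53 | genes detectable in the transcriptome (of 61) |
| `gene_loss_rate` | 0.02 | per-gene, per-homeolog loss probability |
| `host_read_fraction` | 0.0825 | host (E. coli-like) read contamination |

Genes have 1–5 exons (150–600 bp) with 80–400 bp introns, placed
non-overlapping with random spacers. Homeologs are built gene-by-gene so
every gene copy, duplicate and TE insertion is recorded with exact
coordinates (`HomeologTruth`). The TE library is synthetic — random
consensus sequences labeled Gypsy/Copia/DNA (incl. a 146-bp Stowaway
family)/LINE, LTR families carrying literal 300-bp terminal repeats — not
a curated repeat database. TE copies are added (3% mutated) until the
repeat budget `target/(1−target) × backbone` is met, so the realized
fraction lands within ±0.01–0.02 of target; insertions are assigned to
intergenic segments weighted by length.

Clone inserts draw a homeolog uniformly, a length from
Normal(mean 100 kb, sd 15 kb) truncated to [mean/2, 2·mean], and a start
drawn uniformly over an insert-length-extended range then clamped into
bounds. The clamping exists because the simulated region is an excised
window: uniform-interior starts would leave the first and last loci almost
never covered, whereas a real library is prepared from whole chromosomes
and covers the region edges at full depth. The clamp preserves the insert
length distribution exactly and concentrates a small start-position mass
at the window edges.

Sequencing and assembly are deliberately not modeled read-by-read: each
sequencing pool emits one error-free contig per clone insert (coverage ~
Normal around the pool mean) plus ~2.5 decoy contigs per clone (85% of
them 5–49 kb; the rest longer but low-coverage), which reproduces the
shape a pool assembly presents to QC — roughly 60% of contigs fall below
the 50-kb filter. Reads (insert fragments with point errors, vector
carry-over on ~30% of ends, host decoys at the planted fraction) exist to
exercise trimming and decontamination, not to feed an assembler.

### What the synthetic benchmarks do not show

The simulator preserves intron structure 1:1, draws genes as independent
random sequences (no gene families, no segmental duplications beyond the
planted tandems), gives contigs no assembly errors or chimeras, and uses
point-error reads rather than an indel-dominant long-read error profile.
Passing the recovery benchmarks therefore demonstrates that the
*algorithms* are correct under the stated statistical structure — it does
not certify performance on real polyploid data, where paralogy,
mis-assembly and annotation noise add failure modes the generator does not
emulate.

## Benchmark problem sizes

The ground-truth recovery benchmark runs the full gene complement and
divergence structure at 4 homeologs and 400 clones (a 5×10×10 grid), with
homeolog-pair classification evaluated on a seeded sample of 150
overlapping pairs and tandem-duplication detection over all 400 annotated
inserts. The degenerate-limit benchmark (zero divergence, zero repeats,
full transcript detection — the regime where the reconstruction must be
exact) uses 30 genes / 200 kb / 2 homeologs / 120 clones of 40 kb. These
sizes are the package's chosen desk-scale study conditions; all stage
parameters remain at their defaults under them.

## Numerical and degenerate-input conventions

* Empty pool → empty reads/contigs, not an error; zero contigs → a stats
  row of zeros with N50 reported as 0; empty aggregate input is an error.
* GC% excludes N; a sequence of only Ns has GC 0.
* Percentages print to one decimal (filter fraction) or two (GC, host);
  count means round to the nearest integer, matching how such tables are
  conventionally printed.
* The 50-kb contig filter is strict (`< 50,000` removed; exactly 50,000
  kept); published contig sizes with inconsistent "kb" labels are treated
  as bp.
* Ties: best transcript hit → higher identity then smaller id; tiling path
  → longer sequence then smaller id; primer scan → first qualifying pair
  scanning outside-in.
* All randomness flows through numpy Generators keyed by (seed, stage
  constant); identical config + seed reproduces every artifact
  byte-identically (the run manifest records SHA-256 checksums).

## Known limitations

* The exon-chaining annotator assumes introns ≤5 kb (configurable) and
  exons ≥40 bp; genes whose every exon is shorter would be invisible.
* Greedy pool planning can exceed the optimal pool count by one on
  adversarial conflict graphs.
* The homeolog-discrimination thresholds (0.99/0.95 same-overlap,
  0.5 intergenic cutoff) were chosen from the divergence structure of the
  simulated system; real data may need retuning, which is why all four are
  parameters.
* `e_like` is not a calibrated E-value; cross-study comparisons of its
  magnitude are meaningless.
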