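# Small synthetic end-to-end run: 12 genes / 70 kb / 2 homeologs / 40 clones.
# Thresholds that scale with sequence size (contig length filter) are scaled
# to the toy insert size; everything else keeps the package defaults.
seed: 42
outdir: example_out
sim:
  n_genes: 12
  region_length_bp: 70000
  ploidy: 2
  n_tandem_dup_genes: 2
  transcript_detect_count: 12
  gene_loss_rate: 0.0
  seed: 42
n_clones: 40
insert_mean_bp: 16000
insert_sd_bp: 2500
layout: [2, 5, 5]
reads_per_clone: 12
contig_min_len: 9000
max_homeolog_pairs: 30
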