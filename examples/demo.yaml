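# Demo run: one B49 x B73 cross (two replicates), three-line haplotype panel,
# shared chr6 haplotype, recessive QTL at 60 Mb, cross-pooled meta-analysis.
seed: 7
out_dir: demo_run
simulate:
  n_sites_per_chrom: 3000
  divergence: 0.5
  resistant_lines: [B49, B75, B96]
  crosses: [B49]
  n_f2: 200
  n_replicates: 2
  bulk_size: 50
  mean_pool_depth: 4.0
  ibd_segments:
    - {chrom: chr6, start: 7895601, end: 109684471, members: [B49, B75, B96]}
  qtl:
    - {chrom: chr6, pos: 60000000, mode: recessive, variance_explained: 0.70}
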