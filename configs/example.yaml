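# Default end-to-end synthetic run: 360 lines, 6 sub-populations,
# 7 chromosomes x 2000 SNPs, 5 trials (2 spring-sown, 3 winter-sown),
# one sign-flipping QTL (earlier in spring, later in winter).
seed: 7
out_dir: megxe_out
log_level: INFO

simulation:
  n_lines: 360
  n_subpops: 6
  fst_target: 0.15
  n_chrom: 7
  snps_per_chrom: 2000
  n_gene_regions: 20
  polygenic_var: 4.0
  gxe_var: 2.0
  residual_var: 1.0
  prep_fraction: 0.20
  n_blocks: 10
  n_checks: 2
  qtl:
    - [1000, [-3, -3, 3, 3, 3]]

filter:
  min_present: 0.80
  maf_min: 0.05
  min_homozygous: 0.98

ld:
  thin_step: 25
  window_snps: 500
  overlap: 475
  bin_bp: 20000
  quantile: 0.95

structure:
  alpha: 0.05
  n_clusters: 6

gwas:
  alpha: 0.05
  min_carriers: 5
  haplotype_scan: true
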