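# megxe

Genotype-by-environment (G×E) analysis and multi-environment GWAS for
structured, fully inbred crop panels. The package covers the complete
statistical chain from raw genotype matrices to environment-specific
marker and haplotype-state effects:

- **genodata** — VCF / TSV dosage-matrix IO, variant filters (presence ≥
  80%, homozygosity ≥ 98%, MAF ≥ 0.05) and modal imputation.
- **ldkin** — local LD decay along chromosomes (sliding windows of
  thinned markers, binned 0.95-quantile r², monotone non-increasing fit,
  crossing distances at r² = 0.1/0.3), optionally corrected for kinship
  (whitened r²), LD-aware SNP sampling, and the Astle–Balding kinship.
- **structure** — significant principal components by sequential
  Tracy–Widom tests, Ward clustering into sub-populations, per-SNP
  Weir–Cockerham Fst scans with moving medians, and spatial PCA
  (inverse great-circle-distance weights, Moran's I, global/local axes).
- **hapblocks** — Gabriel-style haplotype blocks within gene regions
  (D′ likelihood-profile confidence intervals, Haploview default rules)
  and per-line haplotype-state assignment (states a, b, c, … by
  descending frequency).
- **gxe** — stage-1 adjusted means with generalized (Cullis)
  heritability, two-way REML variance partitioning (G, G×E, residual),
  variance explained by genotype categorizations, Finlay–Wilkinson
  regression, AMMI and GGE biplots, Tukey compact letter displays.
- **gwas** — multi-environment scans with environment-specific SNP or
  haplotype-state substitution effects, leave-one-chromosome-out PC
  correction, per-environment residual variances, joint Wald tests,
  effective-number-of-tests (Li–Ji) thresholds and genomic control.
- **simulate** — structured synthetic panels (Balding–Nichols
  divergence, founder-mosaic LD), geography, gene regions, and
  plot-level phenotypes from augmented p-rep field designs with known
  ground truth for every recovery test.
- **pipeline / cli** — YAML-configured orchestration of all stages with
  per-stage manifests and reproducible seeds.

## CLI

Everything is driven by one YAML config (see `configs/example.yaml`):

```sh
megxe validate -c configs/example.yaml
megxe run-all -c configs/example.yaml --out results/run1 --seed 7
megxe structure -c configs/example.yaml    # run up to the structure stage
```

Stages: `simulate filter ld kinship structure fst spca blocks adjust gxe
gwas`. Each stage writes plain-text tables plus a JSON manifest (stage
parameters, output hashes, seed); rerunning the same config reproduces
every output bit-for-bit.

Instead of a `simulation:` block the config may point at real inputs
(`inputs.genotypes` as VCF or TSV dosage matrix, plus metadata /
phenotype CSVs).

## Library example

```python
from megxe.simulate import SimConfig, simulate_genotype_panel, simulate_trial_phenotypes
from megxe.genodata import filter_variants, impute_modal
from megxe.ldkin import local_ld_decay, ld_aware_sample, kinship_astle_balding
from megxe.structure import significant_pcs, ward_cluster

cfg = SimConfig(seed=1)
panel, truth = simulate_genotype_panel(cfg)
panel, report = filter_variants(panel)
panel = impute_modal(panel)
profile = local_ld_decay(panel)
idx = ld_aware_sample(panel.snp_map, profile, seed=1)
K = kinship_astle_balding(panel, idx)
pcs = significant_pcs(K)
labels, linkage = ward_cluster(pcs.significant_scores, k=6)
```
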