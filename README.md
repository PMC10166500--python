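# stagediv

Analysis toolkit for **between-population developmental gene-expression
divergence** in bulk RNA-seq: how do two populations of the same species
differ in their transcriptional program across developmental stages, which
genes drive the divergence, and is it mirrored by allele-frequency
differentiation at the sequence level?

The canonical design is 2 populations × 3 developmental stages × 3
biological replicates (18 samples) over ~12,000 coding and long non-coding
genes — e.g. a derived European and an ancestral sub-Saharan African
*Drosophila melanogaster* population sampled across ~10 hours of late
larval development in the fat body. The package provides:

* **Expression core** — mean-reads-per-sample filtering (15/sample ⇒ 270
  total reads at 18 samples), median-of-ratios size factors, TPM,
  expression bins, PCA, k-means profile clustering.
* **Differential expression** — a negative-binomial GLM with per-gene
  Cox–Reid-adjusted ML dispersion: Wald contrasts between the six
  population × stage groups, y ~ NB(μ, α), Var = μ + αμ²,
  log₂FC = log₂((q̂_A + ½)/(q̂_B + ½)), and a likelihood-ratio test for the
  stage × population interaction; Benjamini–Hochberg FDR.
* **Dynamics** — per-gene DE classes across populations
  (conserved / private / opposite), transcriptional-turnover divergence
  D = 1 − ρ(log₂FC₁, log₂FC₂), the stage-specificity index
  τ = Σᵢ(1 − xᵢ/x_max)/(n − 1) on mean TPM per stage, and Yates-corrected
  χ² tests for lncRNA contribution and gene-set overlap.
* **Co-expression network** — unsigned soft-threshold adjacency |r|^β
  (β = 6), topological overlap matrix, average-linkage module detection
  with size filter and eigengene merging, module eigengenes, module–trait
  Pearson correlations, kTotal/kWithin connectivity and hub genes.
* **Population genetics** — per-SNP Hudson F_ST, empirical per-arm
  top-5% outlier cutoffs, and per-gene goodness-of-fit χ² enrichment of
  high-F_ST SNPs with BH correction.
* **Mapping-bias diagnostic** — the dual-reference index
  b = (n_pop − n_std)/(n_pop + n_std) with per-group summaries.
* **Synthetic data** — an NB count generator with planted stage, population,
  interaction and stage-specific effects, a Balding–Nichols SNP generator
  with divergence hot spots, and a dual-reference thinning generator, all
  with ground truth, so every stage is testable without external data.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Run the full pipeline on simulated data from a config file:

```yaml
# example.yaml
seed: 7
output_dir: example_out
simulate:
  n_genes: 1000
  n_snps_per_arm: 20000
  dual_bias_fraction: 0.05
thresholds:
  max_network_genes: 500
```

```bash
stagediv run --config example.yaml
```

The consolidated `example_out/report.tsv` from this exact run:

```
quantity                 value
n_genes_input            1000
n_genes_expressed        915
n_samples                18
fdr                      0.05
n_de_calls               1937
n_de_genes_any_contrast  522
n_interaction_genes      48
n_modules                2
n_genes_fst_tested       725
n_genes_fst_enriched     14
divergence_early_vs_late    0.0960676
divergence_early_vs_prepup  0.11273
divergence_late_vs_prepup   0.0900277
```

Reading it: 915 of 1,000 simulated genes pass the 270-read filter; 522
genes are differentially expressed in at least one of the nine canonical
contrasts at 5% FDR and 48 show a significant stage × population
interaction; the co-expression network resolves 2 modules; 14 gene regions
carry a significant excess of high-F_ST SNPs (the simulation planted 20
divergence hot spots, some of which fall below the SNP-count threshold for
testing); and the turnover-divergence statistic D = 1 − ρ is ~0.09–0.11,
i.e. the two simulated populations share most of their between-stage
fold-change structure. Per-stage tables (DE results, DE classes, τ,
lncRNA contribution χ², module assignments, F_ST cutoffs and enrichment,
mapping-bias summaries) are written alongside, each with its parameters in
header comments.

The same stages are available as library functions
(`stagediv.de.de_table`, `stagediv.dynamics.tau_table`,
`stagediv.network.cluster_modules`, `stagediv.fst.gene_region_enrichment`,
…) and as CLI subcommands (`simulate`, `filter`, `tpm`, `bins`, `pca`,
`de`, `run`).

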