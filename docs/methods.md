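# Methods

`stagediv` analyses expression divergence between two populations sampled
across developmental stages in a bulk RNA-seq design, together with the
sequence-level differentiation of the same gene set. This note records the
statistical models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducing results.

## Study design assumed

The canonical design is 2 populations (a derived European population, `NL`,
and an ancestral sub-Saharan African population, `ZI`) × 3 developmental
stages (early wandering larva, late wandering larva, white prepupa) × 3
biological replicates = 18 samples, over ~12,000 genes of which ~6.6% are
lncRNAs. All machinery is parameterised over the actual labels found in
the sample sheet; nothing is hard-wired to this layout except the
interaction test's degrees of freedom, which follow the factor levels.

## Expression filtering and normalisation

A gene is *expressed* when its mean mapped-read count per sample is at
least 15 over all samples of the dataset — equivalently a total of
15 × n_samples reads (270 for 18 samples, 165 for 11). The same
mean-per-sample rule applied within each population × stage cell gives
per-combination expressed calls; the two notions are independent and both
are reported.

Size factors are DESeq-style median-of-ratios: factor_j = median over
reference genes of count_gj / geometric-mean_g, using genes positive in
every sample; when no such gene exists the code falls back to total-count
ratios with a warning. TPM is (c/L) / Σ(c/L) × 10⁶ with L the gene-sheet
effective length; for real annotations we document this column as the
union-exon (whole-gene) length, since transcript-level mapping leaves the
choice open. Expression bins on mean TPM use closed upper bounds:
very low ≤ 1 < low ≤ 10 < moderate ≤ 25 < high ≤ 50 < very high.

PCA operates on log2(count/size-factor + 1) over the 500 most variable
genes. This transform stands in for a variance-stabilising transform;
variance fractions are therefore comparable only qualitatively with
pipelines that use a VST.

## Negative-binomial differential expression

Counts are modelled as y_gj ~ NB(μ_gj, α_g) with variance μ + αμ² and
μ_gj = s_j·q_{g,group(j)}. This is a spec-level NB test in the DESeq2
tradition, not a clone: there is no fold-change shrinkage, no
Cook's-distance outlier handling, no independent filtering and no
dispersion trend. The behavioural contract is calibration and effect
recovery on simulated data, not byte-level agreement with any external
tool.

**Dispersion.** Per-gene maximum likelihood on log α within [10⁻⁸, 10],
with group means profiled as mean normalised counts and a Cox–Reid
adjustment (−½ log det of the mean-parameter information). The CR term
matters: without it the dispersion is biased low at n = 3 per group and
downstream tests become strongly anti-conservative (we measured type-I
error 0.14 at nominal 0.05). A method-of-moments estimate is the fallback
on optimiser failure; all-zero genes are flagged untestable and excluded
from the multiple-testing denominator.

**Wald contrasts.** log2FC = log2((q_A + 0.5)/(q_B + 0.5)); the
pseudo-count 0.5 keeps directions defined when one group is fully silent.
The statistic is the log-ratio over SE = √(1/I_A + 1/I_B) with
I = Σ_j μ_j/(1 + αμ_j), referred to a t distribution with
n_samples − n_groups degrees of freedom. The t reference (rather than
normal) is the standard small-sample correction for plug-in dispersion;
with the 18-sample design it moves measured type-I error from ~0.075 to
0.04–0.05 at nominal 0.05. Significance is strict: padj < FDR.

**Interaction LRT.** Full model stage + population + stage:population
(one mean per cell) versus the additive reduction, both fitted by IRLS
(log link, log size-factor offset, fixed per-gene α). LR/df is referred
to F(df, n − p_full) in the quasi-likelihood tradition; the asymptotic
χ² P is reported alongside. Measured null type-I error is 0.045–0.049
across depths 30–200 versus 0.08–0.10 for the plain χ² reference.

**Multiplicity.** Benjamini–Hochberg within each contrast; missing
P-values (untestable genes) are excluded from m. Magnitude comparisons
between |log2FC| sets use Welch's t-test with Bonferroni correction over
the stated comparison family.

## Dynamics statistics

Between-stage DE calls in the two populations are classified per gene as
conserved (significant in both, same sign), opposite (both, opposite
sign), private to one population, or none; the classes partition the gene
universe. Turnover divergence between populations is D = 1 − ρ of the two
populations' log2 fold-changes for a stage pair, computed over all genes
tested in both populations by default (the gene set is configurable); ρ
is Pearson, with Spearman behind a flag. τ = Σ(1 − x_i/x_max)/(n − 1) on
mean TPM per stage, per population; τ is scale-invariant, 0 for uniform
expression, 1 for single-stage expression, undefined (and counted) when a
gene is silent in all stages of a population.

The lncRNA-contribution and set-overlap tests are Yates-corrected 2×2
chi-square tests. For the contribution test the second row is the whole
analysed dataset (e.g. 816 lncRNA vs 11,615 protein-coding genes); this
exact construction — background row not reduced to the complement, Yates
correction on — reproduces the published P-values for five of the six
per-stage up-regulated sets at printed precision. The sixth (Dutch early)
is not reproducible under any standard 2×2 variant we tried and is
excluded from acceptance checks.

## Co-expression network

Unsigned adjacency a_ij = |cor|^β with β = 6 (the conventional unsigned
default; no scale-free fit scan is performed). Topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), checked against
a brute-force double-loop oracle to 1e-12. Genes are clustered on
1 − TOM with average linkage; the tree is cut statically at the 0.99
quantile of merge heights, clusters under 30 genes are unassigned
("grey"), surviving modules are relabelled by decreasing size with the
conventional colour sequence, and modules whose eigengenes correlate
above 0.95 are merged iteratively. This is deliberately **not** the
published dynamic hybrid tree-cut algorithm; the contract is recovery of
planted block-correlation structure (adjusted Rand ≥ 0.9 for block r ≥
0.8), not replication of a particular module catalogue.

Module eigengenes are first principal components of the per-gene z-scored
module submatrix, sign-aligned with the module mean profile. Module–trait
association uses Pearson r with the student asymptotic P
(t = r√(n−2)/√(1−r²)). Stage age is encoded ordinally (0, 1, 2) by
default because no clock-time values are available; the encoding is a
configuration knob, and with three equally spaced stages any affine
encoding gives identical correlations. Population is encoded 0/1.
Connectivity: kTotal = row sum of adjacency, kWithin = the same within
the gene's module; hubs are the top five kWithin per module, ties broken
by gene ID.

## F_ST and outlier enrichment

Per-SNP differentiation uses the Hudson estimator in ratio form
(numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), denominator
p₁(1−p₂) + p₂(1−p₁)); a Weir–Cockerham variant is available behind a
flag, and the enrichment machinery is estimator-generic. Sites
monomorphic in both populations are undefined and skipped. Outlier
cutoffs are the empirical 95th percentile per chromosome arm (linear
interpolation); a SNP is "high" only when strictly above the cutoff.

Gene regions (1-based inclusive spans) with at least 20 SNPs are tested
with a df = 1 goodness-of-fit chi-square of the observed high-F_ST count
against the flat 5% expectation E = 0.05n, BH-corrected; a gene is
enriched when O > E and padj < 0.05. The minimum of 20 SNPs keeps E ≥ 1;
genes below it, without SNPs, or on the dot (4th) chromosome are reported
untested. We read the expectation as flat 5% of the gene's SNPs rather
than scaled to per-arm totals; with per-arm cutoffs the two readings
coincide up to interpolation ties.

## Mapping-bias index

b = (n_pop − n_std)/(n_pop + n_std) per gene and sample, where n_pop and
n_std are read counts from the population-matched and standard reference.
b ∈ [−1, 1], is invariant under common scaling of both counts and
antisymmetric under swapping them. As the formula is written, +1 means
all reads map only with the population reference. (Descriptions that
attach −1 to the population reference contradict the formula; we
implement the formula verbatim and label orientation from it.) Entries
with both counts zero are excluded from summaries and counted, never
imputed. Histograms use fixed 0.05-wide bins on [−1, 1].

## Synthetic-data generator

The generator is first-class, tested code; every downstream stage is
exercised against its known ground truth.

* **Counts.** NB draws with variance μ + αμ², α = 0.05 by default, log2
  baseline means uniform on [3, 10], log-normal library-size multipliers
  (σ = 0.2) so that median-of-ratios normalisation is actually needed.
  Disjoint gene classes carry planted effects: 30% stage-DE (one stage
  elevated in both populations), 10% population-DE (±2 log2 units in one
  population across stages), 5% interaction (one stage shifted +2 in one
  population and −2 in the other), 5% stage-specific (expressed in
  exactly one stage, silent elsewhere, so τ → 1). The stage-effect
  magnitude is scaled so stage explains ~5× more expression variance
  than population, reproducing the stage-dominant PCA structure of real
  developmental series; the ratio is a config field.
* **SNPs.** Balding–Nichols model: ancestral frequencies uniform on
  (0.05, 0.95), population frequencies Beta-distributed with divergence
  parameter 0.05 genome-wide and 0.40 inside designated hot gene spans;
  binomial allele counts at haploid sample sizes of 20 per population.
  The model is a convenience — any generative process with a tunable
  F_ST gradient would serve — and hot spans may not overlap.
* **Dual-reference counts.** Each true count is independently thinned at
  mapping rate 0.9 per reference; a biased subset has one reference's
  rate multiplied by (1 − strength) with a random sign per gene, so
  strength 1 drives the index to ±1 exactly.

What the generator does **not** emulate: GC/length biases, batch
effects, correlated genes outside planted modules, isoforms, linkage
disequilibrium between SNPs, mutation spectra, or read-level error.
Passing tests therefore demonstrate statistical correctness of the
machinery under its stated model, not robustness to every artefact of
real libraries.

## Problem sizes and numerical choices

Test-suite and acceptance-script simulations use 2,000–5,000 genes and
10,000 SNPs per arm — sizes chosen so each check isolates one property at
comfortable Monte-Carlo precision. Dispersion is clamped to [10⁻⁸, 10];
the Wald information uses pseudo-counted means so silent groups keep a
finite SE; hierarchical-cluster label assignment, hub tie-breaks and
k-means (k-means++ with 10 restarts) are all deterministic given the
seed. The pipeline fans a single global seed out to per-stage seeds by
fixed offsets, so a stage rerun in isolation reproduces its in-pipeline
output; all output TSVs carry the version, seed and parameters in header
comments, and a fixed config yields byte-identical reports.

## Known limitations

* The NB test has no dispersion moderation across genes; at very low
  counts per-gene dispersions are noisy and power suffers relative to
  empirical-Bayes pipelines.
* The static tree cut can split one correlation block across modules
  when within-block correlation is weak (r < ~0.5); the eigengene-merge
  step only partially compensates.
* Real-data headline counts (numbers of DE genes, module catalogues,
  published per-arm cutoffs, τ shifts between specific populations)
  require the original sequencing data and are out of scope; the
  acceptance surface is the property-based contract above.
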