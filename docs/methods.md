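# Methods

## The synthetic study design

The generator (`lnceqtl.synthgen`) emulates a multi-region post-mortem
brain expression cohort: `n_individuals` donors (default 134) each
contribute a sample to every one of `n_tissues` regions (default 10), so
region-level analyses share donors. Defaults are desk-scale in gene and
variant count but keep the dependence structure of the full design.

**Genotypes.** Each gene gets `variants_per_gene` biallelic variants
placed uniformly in its ±1 Mb cis window; genes are spaced 2.5 Mb apart so
cis windows are disjoint. Dosages are Binomial(2, maf) per individual
(Hardy–Weinberg), maf drawn uniform on `maf_range` ⊆ [0.05, 0.5]; columns
whose empirical MAF falls below the 0.05 QC floor are redrawn, so the
post-QC guarantee holds at any n. Two optional structure toggles exist
because downstream methods need them: `ld_block_size > 1` copies
consecutive variants from a latent haplotype with per-allele mutation
probability `ld_mutation_p` (dosage r² ≈ (1 − p)²), for testing LD pruning
and expansion; `pop_diff > 0` splits the cohort into two populations with
allele frequencies shifted by ±pop_diff/2, for testing genotype PCs. There
is no recombination map and no long-range LD.

**Expression.** For lncRNA g in tissue t:
expr = base_g + a·age + b·sex + β_{g,t}·dosage + λ_g·h + ε, with ages
uniform on [40, 90] years, sex Bernoulli(0.5) (an elderly-donor cohort
without claiming any specific study's distribution), a = 0.02 and b = 0.3
log2 units, noise ε ~ N(0, `noise_sd`). A fraction `frac_elnc` of lncRNAs
get one causal cis variant; the effect vector across tissues is
equicorrelated multivariate normal with pairwise correlation
`tissue_share_r` and marginal SD `beta_sd`. With `beta_fixed=True` the
drawn vector is rescaled to RMS magnitude `beta_sd` — used for power-style
experiments where a vanishingly small planted effect would make the
experiment test luck rather than the method. The confounder h is a single
standard-normal donor factor with loadings λ ~ N(0, `confounder_sd`) on
every gene: the minimal structure that biases naive expression-on-expression
regression but not an instrumented fit. mRNAs in a causal pair are
expr = base_m + θ·(parent lncRNA expr) + λ_m·h + ε.

**GWAS.** A fresh virtual cohort of `gwas_n` individuals is resampled at
the same variants; the trait is y = Σ_g θ_g·(tissue-averaged genetic value
of lncRNA g) + ε and per-variant marginal OLS gives (beta, se, z). With no
trait effects the z-scores are standard normal.

**Annotations.** Disease sets are Bernoulli memberships with
odds(true eSNP)/odds(other) equal to `disease_or` at base rate
`disease_base_rate`; TF peaks tile a `peak_fraction` of the genome with
extra peaks dropped on true eSNPs at rate `peak_fraction · peak_esnp_bias`.

What the generator does *not* emulate: probe-level measurement, LD with
realistic decay, allele-frequency spectra, sample dropout across regions,
polygenic trait architecture beyond the mediated term. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under its stated assumptions, not that real-data effect sizes or counts
will be reproduced.

## Covariates and preprocessing

Genotype PCs come from the SVD of the column-standardized dosage matrix
(zero-variance variants dropped; sign fixed by making the largest-magnitude
loading positive). Hidden expression factors are PCs of
covariate-residualized expression — a deterministic surrogate for
variational factor models such as PEER; it recovers broad batch axes but
does not model uncertainty, and on pure noise its variance explained
tracks the Marchenko–Pastur edge (guarded by a test). The default factor
count is min(15, n_samples/10) — 15 for cohorts of ≥ 150 samples,
proportionally fewer at desk scale to avoid overfitting — and the pipeline
additionally caps it at n_genes/10, because with few genes the factors
absorb per-gene signal rather than shared structure. Residualization is
per-gene OLS with intercept; it is idempotent and exactly orthogonal to
the covariates. Cross-region outlier screening Z-scores residualized
expression per gene (population SD, ddof 0 — the convention is fixed for
determinism), takes the per-donor median across regions, and flags a gene
iff some donor's |median Z| is strictly greater than the threshold
(default 2).

## Cis mapping and calling

Nominal fits use the Frisch–Waugh identity: expression and dosages are
residualized on the covariates once, and the per-pair slope on residualized
data equals the full-model OLS slope; t-tests use df = n − p of the full
model. p-values are floored at 1e-300. The permutation null shuffles
residualized expression (not raw, preserving the covariate structure) with
one shared permutation per round so per-gene minima are comparable; the
empirical p uses the (1+k)/(1+n_perm) convention with ties counted as
exceedances (conservative). Default n_perm = 1000; tests and the
acceptance script use 200, which bounds the empirical-p granularity at
1/201. The elncRNA rule is BH q < 0.05 by default (`elnc_rule="raw"`
switches to empirical p < 0.05). eSNPs are enumerated only within
elncRNAs; the per-gene threshold is the linear-interpolation 5th
percentile of the permuted minima.

## Enrichment machinery

The exact test is scipy's two-sided Fisher (point-probability ordering,
ties included); the reported OR is the cross-product (not conditional MLE)
with the Haldane 0.5 correction applied only when a zero cell exists, and
the CI is Woolf's log-OR ± 1.96·SE on the corrected counts — deterministic
and matching the OR + CI presentation style of enrichment figures.
Functional classes use the precedence splicing > exonic > UTR5 > UTR3 >
ncRNA_splicing > ncRNA_exonic > intronic > ncRNA_intronic > upstream >
downstream > intergenic, with "splicing" = within 2 bp of an exon boundary
inside an intron and flanks of 1 kb; the oracle test re-derives every class
by independent interval logic. LD pruning is a greedy positional scan
(window 500 retained variants); expansion returns all candidates with
r² > threshold to any index variant plus the index set; r² is computed on
mean-imputed, centered dosages, and in real mode the LD reference is the
supplied genotype panel itself. TF-peak membership is plain interval
overlap of the variant position. MAF bins are half-open 5% bins covering
[0.05, 0.50] (the top edge closed); the trend regresses the per-bin median
eSNP proportion (median over tissues for per-tissue input) on bin
midpoints, excluding empty bins.

## Regional statistics

Differential expression is a per-gene Welch t-test of one region versus
all other regions pooled, on log2 values, with BH across genes and the
joint rule |log2FC| > log2(1.5) and q < 0.05. This is a deterministic,
dependency-free stand-in for moderated-statistic DE packages; with tens of
samples per side the moderation matters little, and donor repetition
across regions is ignored (no mixed model) — a simplification that makes
region-vs-rest p-values slightly optimistic. The rb estimator uses
per-gene top associations from tissue A matched to the same pair in B;
r_e comes from z-score correlation at null variants (p > 0.5 in both
tissues); variances use ddof 0 consistently; rb is clamped to [−1, 1] with
a flag and errors out when error variance exceeds effect variance. The
jackknife SE is leave-one-gene-out with r_e held fixed.

## TWAS

Elastic-net mixing is fixed at 0.5 with the penalty chosen by internal CV
(50-alpha path); an outer K-fold (default 10) refits per split and scores
held-out samples, giving cv_r and its t-based p. The retention rule
(cv r > 0.1, cv p < 0.05) follows prediction-model-repository practice.
The summary z uses the LD-reference dosage covariance with mean imputation
and no shrinkage — desk-scale panels are full rank by construction; a
shrinkage option would be needed for panels with more variants than
samples. Both significance tiers (p < 0.05, q < 0.1) are emitted per gene.

## Causal scan

Instruments are the lncRNA's eSNPs LD-pruned at r² > 0.8 (redundant
instruments add noise, not information). SEs are homoskedastic 2SLS
residual-based (residuals from observed, not fitted, exposure; df = n − p);
a robust option is not currently exposed. F < 10 flags but does not
suppress estimates. The library API accepts any covariate matrix, but the
pipeline passes only known covariates and genotype PCs to the 2SLS stage:
hidden factors are linear functions of the expression matrix, and at
desk-scale gene counts conditioning on them is conditioning on the
exposure and outcome themselves (a collider), which manufactured spurious
causal pairs in end-to-end runs; dropping them restored exact agreement
with ground truth. With thousands of genes the contamination per gene is
negligible and the choice would matter less. Pathway readout applies the
selection rule TWAS q < 0.1 and > 20 significantly affected mRNAs, then
preranked GSEA (weight exponent 1 on |score|, gene-label permutations,
two-sided |ES| exceedance p with the +1 convention, NES = ES / mean same-
sign |permuted ES|) and upper-tail hypergeometric tests.

## Numerical and I/O conventions

Internal coordinates are 1-based inclusive everywhere; BED converts at the
boundary (a BED record `chr1 999 2000 . 0 -` becomes the interval
[1000, 2000] with TSS 2000). Missing dosages are mean-imputed for LD and
PCA; TSVs use '.' for missing, 6 significant digits, scientific notation
for p-values, and carry config hash, seed and n_perm in header comments.
Ties in GSEA ranking break by gene id; BH is statsmodels' step-up. Every
stochastic operation takes an explicit seed (package default 17) and
identical config + seed reproduces all outputs bit-identically.

## Problem sizes used in the test and acceptance suites

Calibration: 200 genes × 50 cis variants, n = 100, 200 permutations,
averaged over 3 replicate null studies (the single-study fraction has
binomial sd ≈ 0.015; averaging estimates the same quantity with less
noise). FDR mixture: 100 genes, 20% true at β = 1, n = 150, 5 replicates.
2SLS: θ = 0.5, n = 500, 20 replicates. rb: 300 genes, error SD = 0.5 ×
effect SD, 20 replicates. TWAS concordance: 40 genes (20 mediated),
n = 3000. Exact-test oracles sweep all 2×2 tables with margins ≤ 12 and
enumerate rank-sum/hypergeometric distributions exhaustively at n ≤ 12.

## Known limitations

No trans-eQTL or conditional secondary-signal mapping; no colocalization
or pleiotropy-robust (Egger/median) estimators; no mixed models for donor
repetition; the PEER surrogate is PCA; LD in the generator is block-wise
and short-range only; real-mode LD uses the analysis panel rather than an
external reference.
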