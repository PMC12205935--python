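# lnceqtl

Genetic regulation of long non-coding RNA (lncRNA) expression, end to end:
permutation-calibrated cis-eQTL mapping, eSNP/elncRNA characterization and
enrichment scans, cross-tissue sharing statistics, summary-statistic TWAS,
and two-stage least squares (2SLS) estimation of lncRNA → mRNA causal
effects. The package is aimed at statistical geneticists who want the full
analysis chain — from dosage matrix to causal-pair table — as tested,
reusable library code, exercised against a synthetic multi-tissue data
generator with queryable ground truth.

## The statistics at the core

**Cis-eQTL mapping with a permutation minimum-p null.** For each lncRNA
*g* and variant *j* within ±1 Mb of the strand-aware TSS, fit

    expr_g = α + β_gj · dosage_j + γᵀ covariates + ε

and test the dosage slope (two-sided t, df = n − p). Covariates are age,
sex, genotype principal components, and hidden expression factors (PCs of
covariate-residualized expression). The per-gene null is the distribution
of the minimum nominal p across cis variants under sample-label
permutation of residualized expression, one shared permutation per round.
The empirical p is (1 + #{permuted min-p ≤ observed}) / (n_perm + 1); genes
with BH q < 0.05 are **elncRNAs**, and their **eSNPs** are the cis variants
with nominal p at or below the empirical 5th percentile of the permuted
minima. Variants with nominal p > 0.5 for every gene, LD-pruned at
r² > 0.8, form the **non-eSNP** background.

**Enrichment.** Every scan — 11-class functional annotation, TF peaks,
5%-wide MAF bins over [0.05, 0.50], and LD-expanded disease risk loci —
reduces to the same 2×2 machinery: two-tailed Fisher's exact p,
cross-product odds ratio with Haldane correction on zero cells, Woolf 95%
CI, BH across tests.

**Cross-tissue sharing.** Jaccard indices of per-region elncRNA sets, and
the error-corrected effect correlation

    r_b = [cov(b₁, b₂) − r_e · mean(se₁·se₂)] /
          √[(var(b₁) − mean(se₁²)) (var(b₂) − mean(se₂²))]

where r_e, the error correlation from shared donors, is estimated from
z-scores at null variants, and the SE is a leave-one-gene-out jackknife.

**TWAS.** Elastic-net cis predictors (retained when CV r > 0.1 and
p < 0.05) are combined with GWAS summary z-scores via
z = Σ w_k σ_k z_k / σ_g, σ_g² = wᵀΣw, with σ and Σ from an LD reference.

**2SLS.** A lncRNA's LD-pruned eSNPs instrument its expression (stage 1);
stage 2 regresses mRNA expression on the fitted values. Because genotypes
are assigned at meiosis, the estimate is robust to hidden confounders that
bias naive co-expression; the first-stage F flags weak instruments
(F < 10). Downstream gene sets are tested by preranked GSEA and
hypergeometric overlap.

## Worked example

```python
from lnceqtl import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(
    sim=SimConfig(n_individuals=100, n_tissues=3, n_lnc=15, n_mrna=10,
                  variants_per_gene=12, frac_elnc=0.4, beta_sd=1.2,
                  beta_fixed=True, theta=0.8, gwas_n=2000, seed=3),
    n_perm=200, seed=3)
b = run_pipeline(cfg)
print({t: len(c.elncrnas) for t, c in b.calls.items()})
print(b.twas_table[["gene", "z", "p", "q"]])
print([(e.lnc, e.mrna, round(e.beta_iv, 2)) for e in b.causal_estimates
       if e.q is not None and e.q < 0.05])
```

prints

```
{'T00': 3, 'T01': 6, 'T02': 4}
   gene         z             p             q
LNC0005 17.637046  1.279786e-69  1.919679e-69
LNC0010 22.103097 2.951148e-108 8.853444e-108
LNC0014  3.141143  1.682901e-03  1.682901e-03
[('LNC0005', 'PCG0009', 0.89), ('LNC0010', 'PCG0000', 0.73), ('LNC0014', 'PCG0001', 1.02)]
```

Of 6 lncRNAs simulated with true cis effects, 3–6 are called per tissue at
this sample size; the three TWAS hits are trait-mediating elncRNAs, and the
three significant 2SLS pairs are exactly the planted causal pairs of those
hits (θ = 0.8; estimates 0.73–1.02), with no false pairs.

The same pipeline runs from files (`mode="real"`): VCF or dosage TSV
genotypes, per-tissue expression TSVs, BED gene models, GWAS summary TSV,
disease-set TSV, peak BED. A thin CLI wraps the library:

```sh
lnceqtl simulate --config cfg.yaml --outdir inputs/   # materialize synthetic inputs
lnceqtl run      --config cfg.yaml --outdir results/  # full pipeline, TSV outputs
lnceqtl report   --outdir results/
```

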