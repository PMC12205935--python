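"""Synthetic multi-tissue lncRNA eQTL study generator with known ground truth.

Emulates the statistical structure the downstream analyses assume: biallelic
dosages under Hardy-Weinberg equilibrium with MAF >= 0.05, per-tissue lncRNA
expression driven by cis variants whose true effects are shared across
tissues at a configurable correlation, known covariates (age, sex) plus a
hidden donor-level confounder, mRNA expression causally downstream of
lncRNAs (sharing the confounder, so naive regression is biased but an
instrumented fit is not), marginal GWAS summary z-scores for a trait
mediated by lncRNA expression, and annotation bundles (functional
intervals, TF peaks, disease SNP sets) with configurable enrichment.

Every generator takes an explicit seed and is bit-reproducible for a fixed
``SimConfig`` + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    LNC_BIOTYPES,
    AnnotationBundle,
    ExpressionPanel,
    GeneModel,
    GenotypeMatrix,
    GroundTruth,
    GwasSummary,
    TissueExpression,
)

logger = logging.getLogger(__name__)

_GENE_SPACING = 2_500_000  # bp between TSSs; keeps +-1 Mb cis windows disjoint
_GENES_PER_CHROM = 40
_CIS_WINDOW = 1_000_000


@dataclass(frozen=True)
class CovariateSpec:
    """Donor covariate distributions and their expression effects.

    Ages uniform on [40, 90] years and sex ~ Bernoulli(0.5) describe an
    elderly post-mortem donor cohort; the betas are log2-expression effects.
    """

    age_range: tuple[float, float] = (40.0, 90.0)
    sex_p: float = 0.5
    age_beta: float = 0.02
    sex_beta: float = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Study design for the synthetic generator.

    Defaults mirror a 134-donor, 10-region brain cohort at desk scale:
    fewer genes and variants, but the same dependence structure.
    """

    n_individuals: int = 134
    n_tissues: int = 10
    n_lnc: int = 60
    n_mrna: int = 40
    variants_per_gene: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_elnc: float = 0.2
    beta_sd: float = 0.6
    beta_fixed: bool = False  # plant effects at magnitude beta_sd (RMS), not N(0, beta_sd)
    tissue_share_r: float = 0.7
    n_causal_pairs: int = 5
    theta: float = 0.5
    confounder_sd: float = 0.5
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    noise_sd: float = 1.0
    gwas_n: int = 5000
    seed: int = 17
    # optional structure toggles
    ld_block_size: int = 1  # >1 generates correlated variants in blocks
    ld_mutation_p: float = 0.05
    pop_diff: float = 0.0  # two-population allele-frequency differential
    # annotation-bundle knobs
    n_diseases: int = 5
    disease_or: float = 3.0
    disease_base_rate: float = 0.05
    n_tfs: int = 3
    peak_fraction: float = 0.1
    peak_width: int = 500
    peak_esnp_bias: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within [0.05, 0.5], got {self.maf_range}")
        if not (0.0 <= self.frac_elnc <= 1.0):
            raise ValueError("frac_elnc must be in [0, 1]")
        for name in ("n_individuals", "n_tissues", "n_lnc", "n_mrna", "variants_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_causal_pairs > self.n_lnc * self.n_mrna:
            raise ValueError("n_causal_pairs exceeds n_lnc * n_mrna")
        if self.disease_or < 0:
            raise ValueError("disease_or must be >= 0")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


def with_overrides(cfg: SimConfig, **kwargs) -> SimConfig:
    return replace(cfg, **kwargs)


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(cfg: SimConfig) -> list[GeneModel]:
    """Deterministic gene layout: lncRNAs and mRNAs interleaved, spaced so
    each gene's +-1 Mb cis window contains only its own variants.

    lncRNA biotypes cycle through the six subtypes; protein-coding genes
    carry an interior CDS so UTR annotation is decidable.
    """
    genes: list[GeneModel] = []
    specs = [("lnc", i) for i in range(cfg.n_lnc)] + [("mrna", i) for i in range(cfg.n_mrna)]
    # interleave lnc and mrna genes along the genome
    order: list[tuple[str, int]] = []
    li, mi = 0, 0
    for k in range(len(specs)):
        if (k % 2 == 0 and li < cfg.n_lnc) or mi >= cfg.n_mrna:
            order.append(("lnc", li))
            li += 1
        else:
            order.append(("mrna", mi))
            mi += 1
    for k, (kind, i) in enumerate(order):
        chrom = f"chr{k // _GENES_PER_CHROM + 1}"
        anchor = _CIS_WINDOW + 10_000 + (k % _GENES_PER_CHROM) * _GENE_SPACING
        strand = "+" if k % 2 == 0 else "-"
        exons = [(anchor, anchor + 2_000), (anchor + 6_000, anchor + 20_000)]
        tss = anchor if strand == "+" else anchor + 20_000
        if kind == "lnc":
            biotype = LNC_BIOTYPES[i % len(LNC_BIOTYPES)]
            gid = f"LNC{i:04d}"
            cds = None
        else:
            biotype = "protein_coding"
            gid = f"PCG{i:04d}"
            cds = (anchor + 500, anchor + 15_000)
        genes.append(GeneModel(gid, biotype, chrom, strand, tss, exons, cds))
    return genes


def cis_variant_ids(gene: GeneModel, geno: GenotypeMatrix, window: int = _CIS_WINDOW) -> list[str]:
    v = geno.variants
    m = (v["chrom"] == gene.chrom) & (np.abs(v["pos"] - gene.tss) <= window)
    return list(v.loc[m, "variant_id"])


# ---------------------------------------------------------------------------
# genotypes


def _draw_block(
    rng, n: int, maf: float, size: int, mut_p: float, pop_split=None, pop_diff: float = 0.0
) -> np.ndarray:
    """One LD block: ``size`` variants copied from a latent haplotype pair,
    each allele independently replaced with a fresh Bernoulli(maf) draw with
    probability ``mut_p`` (preserves marginal frequency, induces r^2 ~ (1-mut_p)^2)."""
    if pop_split is None:
        freqs = np.full(n, maf)
    else:
        freqs = np.where(
            pop_split,
            np.clip(maf + pop_diff / 2, 0.01, 0.99),
            np.clip(maf - pop_diff / 2, 0.01, 0.99),
        )
    lat = rng.random((n, 2)) < freqs[:, None]
    cols = np.empty((n, size), dtype=np.int8)
    for j in range(size):
        mut = rng.random((n, 2)) < mut_p
        fresh = rng.random((n, 2)) < freqs[:, None]
        alleles = np.where(mut, fresh, lat)
        cols[:, j] = alleles.sum(axis=1)
    return cols


def simulate_genotypes(
    cfg: SimConfig,
    genes: list[GeneModel] | None = None,
    seed: int | None = None,
    n_individuals: int | None = None,
) -> GenotypeMatrix:
    """HWE dosages: per variant, Binomial(2, maf) i.i.d. across individuals.

    Variants are placed so every gene has exactly ``cfg.variants_per_gene``
    cis variants. Columns whose empirical MAF falls below the 0.05 QC floor
    are redrawn so the post-QC guarantee holds at any sample size. With
    ``ld_block_size > 1`` consecutive variants within a gene are correlated
    via a shared latent haplotype; with ``pop_diff > 0`` the cohort splits
    into two populations with shifted allele frequencies.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if genes is None:
        genes = simulate_gene_models(cfg)
    n = cfg.n_individuals if n_individuals is None else n_individuals
    samples = [f"D{i:04d}" for i in range(n)]
    pop_split = None
    if cfg.pop_diff > 0:
        pop_split = np.arange(n) >= n // 2

    recs = []
    cols = []
    for gene in genes:
        lo = max(1, gene.tss - _CIS_WINDOW)
        hi = gene.tss + _CIS_WINDOW
        pos = set()
        while len(pos) < cfg.variants_per_gene:
            pos.update(rng.integers(lo, hi + 1, size=cfg.variants_per_gene - len(pos)).tolist())
        pos = sorted(pos)
        j = 0
        while j < len(pos):
            size = min(cfg.ld_block_size, len(pos) - j)
            maf = rng.uniform(*cfg.maf_range)
            for _ in range(200):
                if cfg.ld_block_size > 1:
                    block = _draw_block(
                        rng, n, maf, size, cfg.ld_mutation_p, pop_split, cfg.pop_diff
                    )
                elif cfg.pop_diff > 0:
                    freqs = np.where(
                        pop_split,
                        np.clip(maf + cfg.pop_diff / 2, 0.01, 0.99),
                        np.clip(maf - cfg.pop_diff / 2, 0.01, 0.99),
                    )
                    block = (
                        (rng.random((n, 2, size)) < freqs[:, None, None]).sum(axis=1).astype(np.int8)
                    )
                else:
                    block = rng.binomial(2, maf, size=(n, size)).astype(np.int8)
                af = block.mean(axis=0) / 2.0
                mafs = np.minimum(af, 1 - af)
                if np.all(mafs >= 0.05):
                    break
            else:
                raise RuntimeError("could not draw a block passing the MAF >= 0.05 QC")
            for s in range(size):
                recs.append((gene.chrom, pos[j + s], float(mafs[s])))
            cols.append(block)
            j += size

    dosages = np.concatenate(cols, axis=1)
    var = pd.DataFrame(recs, columns=["chrom", "pos", "maf_observed"])
    # global sort by chromosome then position (strictly increasing per chrom)
    order = np.lexsort((var["pos"], var["chrom"].str.removeprefix("chr").astype(int)))
    var = var.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]
    var.insert(0, "variant_id", [f"v{i:06d}" for i in range(len(var))])
    return GenotypeMatrix(dosages, var, samples)


def resample_genotypes(geno: GenotypeMatrix, n: int, seed: int) -> GenotypeMatrix:
    """Fresh HWE cohort at the same variants, using each column's empirical
    allele frequency. Used to build large virtual GWAS cohorts."""
    rng = np.random.default_rng(seed)
    p = geno.dosages.mean(axis=0) / 2.0
    dos = rng.binomial(2, p, size=(n, geno.n_variants)).astype(np.int8)
    af = dos.mean(axis=0) / 2.0
    var = geno.variants.copy()
    var["maf_observed"] = np.minimum(af, 1 - af)
    return GenotypeMatrix(dos, var, [f"G{i:06d}" for i in range(n)])


# ---------------------------------------------------------------------------
# expression


def _equicorrelated_effects(rng, n_tissues: int, r: float, sd: float) -> np.ndarray:
    """One draw of a true effect vector across tissues with pairwise
    correlation ``r`` and marginal SD ``sd``."""
    if n_tissues == 1:
        return np.array([rng.normal(0.0, sd)])
    if r < -1.0 / (n_tissues - 1) or r > 1.0:
        raise ValueError(f"tissue_share_r={r} infeasible for {n_tissues} tissues")
    if 0.0 <= r <= 1.0:
        z0 = rng.normal()
        z = rng.normal(size=n_tissues)
        return sd * (np.sqrt(r) * z0 + np.sqrt(1.0 - r) * z)
    cov = np.full((n_tissues, n_tissues), r) + (1 - r) * np.eye(n_tissues)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_tissues))
    return sd * (L @ rng.normal(size=n_tissues))


def simulate_expression_panel(
    geno: GenotypeMatrix,
    genes: list[GeneModel],
    cfg: SimConfig,
    seed: int | None = None,
) -> tuple[ExpressionPanel, GroundTruth]:
    """Multi-tissue log2 expression with known cis effects and confounding.

    For lncRNA g in tissue t:
        expr = base_g + a*age + b*sex + sum_j beta_{g,j,t} * dosage_j
               + lambda_g * h + eps,   eps ~ N(0, noise_sd)
    with h a standard-normal donor factor shared with mRNAs. For each causal
    pair (l, m): mRNA expr = base_m + theta * expr_l + lambda_m * h + eps.
    The shared h biases naive lnc~mRNA regression; instruments remove it.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    donors = list(geno.samples)
    n = len(donors)
    cs = cfg.covariate_spec
    age = rng.uniform(*cs.age_range, size=n)
    sex = rng.binomial(1, cs.sex_p, size=n).astype(float)
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=donors)
    h = rng.normal(size=n)

    lnc_genes = [g for g in genes if not g.is_coding]
    mrna_genes = [g for g in genes if g.is_coding]
    if len(lnc_genes) != cfg.n_lnc or len(mrna_genes) != cfg.n_mrna:
        raise ValueError("gene models do not match SimConfig gene counts")
    tissue_ids = [f"T{t:02d}" for t in range(cfg.n_tissues)]
    gene_ids = [g.gene_id for g in genes]

    # choose elncRNAs and their causal cis variants
    n_elnc = int(round(cfg.frac_elnc * cfg.n_lnc))
    elnc_idx = rng.choice(cfg.n_lnc, size=n_elnc, replace=False) if n_elnc else np.array([], int)
    true_effects: dict[tuple[str, str, str], float] = {}
    effect_plan: dict[str, tuple[str, np.ndarray]] = {}
    for i in sorted(elnc_idx.tolist()):
        g = lnc_genes[i]
        cis = cis_variant_ids(g, geno)
        if not cis:
            raise ValueError(f"{g.gene_id} has no cis variants")
        v = cis[int(rng.integers(len(cis)))]
        betas = _equicorrelated_effects(rng, cfg.n_tissues, cfg.tissue_share_r, cfg.beta_sd)
        if cfg.beta_fixed:
            # power-study planting: rescale so the effect magnitude is
            # exactly beta_sd (RMS across tissues), keeping the sharing
            # structure and random signs
            betas = betas * (cfg.beta_sd / np.sqrt(np.mean(betas**2)))
        effect_plan[g.gene_id] = (v, betas)
        for t, b in zip(tissue_ids, betas):
            true_effects[(g.gene_id, v, t)] = float(b)

    # causal lnc -> mRNA pairs; parents drawn from elncRNAs when available
    parents_pool = [lnc_genes[i].gene_id for i in sorted(elnc_idx.tolist())] or [
        g.gene_id for g in lnc_genes
    ]
    mrna_pool = [g.gene_id for g in mrna_genes]
    if cfg.n_causal_pairs > len(mrna_pool):
        raise ValueError("n_causal_pairs exceeds available distinct mRNA targets")
    targets = rng.choice(len(mrna_pool), size=cfg.n_causal_pairs, replace=False)
    causal_pairs = {
        (parents_pool[int(rng.integers(len(parents_pool)))], mrna_pool[int(m)]): float(cfg.theta)
        for m in targets
    }

    loadings = {gid: float(rng.normal(0.0, cfg.confounder_sd)) for gid in gene_ids}
    baselines = {gid: float(rng.normal(6.0, 1.0)) for gid in gene_ids}

    tissues: dict[str, TissueExpression] = {}
    for t in tissue_ids:
        sample_ids = [f"{t}:{d}" for d in donors]
        expr = np.empty((len(gene_ids), n))
        lnc_expr_cache: dict[str, np.ndarray] = {}
        row = {gid: k for k, gid in enumerate(gene_ids)}
        for g in lnc_genes:
            e = (
                baselines[g.gene_id]
                + cs.age_beta * age
                + cs.sex_beta * sex
                + loadings[g.gene_id] * h
                + rng.normal(0.0, cfg.noise_sd, size=n)
            )
            if g.gene_id in effect_plan:
                v, betas = effect_plan[g.gene_id]
                e = e + betas[tissue_ids.index(t)] * geno.dosage(v)
            lnc_expr_cache[g.gene_id] = e
            expr[row[g.gene_id]] = e
        parent_of = {m: l for (l, m) in causal_pairs}
        for g in mrna_genes:
            e = (
                baselines[g.gene_id]
                + loadings[g.gene_id] * h
                + rng.normal(0.0, cfg.noise_sd, size=n)
            )
            if g.gene_id in parent_of:
                theta = causal_pairs[(parent_of[g.gene_id], g.gene_id)]
                e = e + theta * lnc_expr_cache[parent_of[g.gene_id]]
            expr[row[g.gene_id]] = e
        mat = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
        tissues[t] = TissueExpression(t, mat, dict(zip(sample_ids, donors)))

    panel = ExpressionPanel(tissues, gene_ids, covariates)
    truth = GroundTruth(
        true_effects=true_effects,
        causal_pairs=causal_pairs,
        confounder_loadings=loadings,
        factor_scores=pd.DataFrame({"h": h}, index=donors),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# annotations


def simulate_annotation_bundle(
    genes: list[GeneModel],
    geno: GenotypeMatrix,
    truth: GroundTruth,
    cfg: SimConfig,
    seed: int | None = None,
) -> AnnotationBundle:
    """Disease SNP sets with configurable enrichment for true eSNPs, TF peak
    interval sets with configurable coverage and eSNP bias, and functional
    intervals derived from the gene models.

    Disease membership is Bernoulli with odds(true eSNP)/odds(other) equal to
    ``cfg.disease_or`` at base rate ``cfg.disease_base_rate``.
    """
    if cfg.disease_or < 0:
        raise ValueError("disease_or must be >= 0")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    vids = geno.variants["variant_id"].to_numpy()
    is_true = np.isin(vids, sorted(truth.effect_variants()))
    p0 = cfg.disease_base_rate
    odds1 = cfg.disease_or * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    probs = np.where(is_true, p1, p0)

    disease_sets: dict[str, set[str]] = {}
    for d in range(cfg.n_diseases):
        for _ in range(1000):
            member = rng.random(len(vids)) < probs
            if member.any():
                break
        disease_sets[f"disease{d:02d}"] = set(vids[member])

    tf_peaks: dict[str, pd.DataFrame] = {}
    if cfg.peak_fraction > 0:
        var = geno.variants
        true_pos = var.loc[is_true, ["chrom", "pos"]]
        for k in range(cfg.n_tfs):
            rows = []
            for chrom, sub in var.groupby("chrom", sort=False):
                span_lo, span_hi = int(sub["pos"].min()), int(sub["pos"].max())
                n_peaks = max(1, int(cfg.peak_fraction * (span_hi - span_lo) / cfg.peak_width))
                starts = rng.integers(span_lo, max(span_lo + 1, span_hi - cfg.peak_width), size=n_peaks)
                for s in np.sort(starts):
                    rows.append((chrom, int(s), int(s) + cfg.peak_width - 1))
            # biased extra peaks centered on true eSNPs
            p_extra = min(1.0, cfg.peak_fraction * cfg.peak_esnp_bias)
            for _, r in true_pos.iterrows():
                if rng.random() < p_extra:
                    s = int(r["pos"]) - cfg.peak_width // 2
                    rows.append((r["chrom"], max(1, s), max(1, s) + cfg.peak_width - 1))
            tf_peaks[f"TF{k}"] = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    func_rows = []
    for g in genes:
        for s, e in g.exons:
            func_rows.append((g.chrom, s, e, f"{g.biotype}:exon"))
    functional = pd.DataFrame(func_rows, columns=["chrom", "start", "end", "label"])
    return AnnotationBundle(functional, tf_peaks, disease_sets)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def simulate_gwas_summary(
    geno_large: GenotypeMatrix,
    truth: GroundTruth,
    cfg: SimConfig,
    seed: int | None = None,
    trait_effects: dict[str, float] | None = None,
) -> GwasSummary:
    """Marginal per-variant association statistics for a trait mediated by
    lncRNA expression.

    The phenotype in the virtual cohort is
        y = sum_g theta_g * (genetic value of lncRNA g) + eps
    where the genetic value is the tissue-averaged true cis effect times
    dosage. ``trait_effects`` maps lncRNA -> theta_g; None means a null
    trait (all zero).
    """
    n = geno_large.n_individuals
    if n < 30:
        raise ValueError("GWAS cohort size below 30: asymptotics unusable")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    G = geno_large.dosages.astype(float)
    y = rng.normal(size=n)
    if trait_effects:
        mean_beta: dict[tuple[str, str], list[float]] = {}
        for (g, v, _t), b in truth.true_effects.items():
            mean_beta.setdefault((g, v), []).append(b)
        for (g, v), bs in mean_beta.items():
            theta = trait_effects.get(g, 0.0)
            if theta:
                y = y + theta * float(np.mean(bs)) * geno_large.dosage(v)

    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ss = (Gc * Gc).sum(axis=0)
    ss = np.where(ss == 0, np.nan, ss)
    beta = (Gc.T @ yc) / ss
    rss = float(yc @ yc) - beta**2 * ss
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / ss)
    z = beta / se
    table = pd.DataFrame(
        {
            "variant_id": geno_large.variants["variant_id"],
            "z": z,
            "beta": beta,
            "se": se,
            "n": n,
        }
    )
    return GwasSummary(table)
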