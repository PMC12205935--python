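"""Generator contracts: HWE dosages, determinism, ground-truth bookkeeping."""

import numpy as np
import pytest
from scipy import stats as sps

from lnceqtl.synthgen import (
    SimConfig,
    resample_genotypes,
    simulate_annotation_bundle,
    simulate_expression_panel,
    simulate_gene_models,
    simulate_genotypes,
    simulate_gwas_summary,
    cis_variant_ids,
    with_overrides,
)


def _cfg(**kw) -> SimConfig:
    base = dict(n_individuals=50, n_tissues=2, n_lnc=6, n_mrna=4,
                variants_per_gene=8, n_causal_pairs=2, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestGenotypes:
    def test_dosages_are_allele_counts_with_symmetric_mean_at_maf_half(self):
        cfg = _cfg(maf_range=(0.5, 0.5), n_individuals=2000, n_lnc=1, n_mrna=1,
                   variants_per_gene=5, n_causal_pairs=1)
        geno = simulate_genotypes(cfg, seed=0)
        assert set(np.unique(geno.dosages)) <= {0, 1, 2}
        assert np.allclose(geno.dosages.mean(axis=0), 1.0, atol=0.07)

    def test_same_config_and_seed_is_bit_identical(self):
        cfg = _cfg()
        a = simulate_genotypes(cfg, seed=3)
        b = simulate_genotypes(cfg, seed=3)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)

    def test_empirical_frequency_within_exact_binomial_bounds(self):
        # n=10000 individuals => 20000 allele draws at p=0.3; the observed
        # allele count must fall inside the central 99.9% binomial interval
        cfg = _cfg(maf_range=(0.3, 0.3), n_individuals=10_000, n_lnc=1, n_mrna=1,
                   variants_per_gene=3, n_causal_pairs=1)
        geno = simulate_genotypes(cfg, seed=5)
        n_alleles = 2 * cfg.n_individuals
        lo = sps.binom.ppf(0.0005, n_alleles, 0.3) / n_alleles
        hi = sps.binom.ppf(0.9995, n_alleles, 0.3) / n_alleles
        freqs = geno.dosages.mean(axis=0) / 2.0
        assert np.all((freqs >= lo) & (freqs <= hi))

    def test_maf_qc_floor_and_sorted_positions(self):
        cfg = _cfg(maf_range=(0.05, 0.08), n_individuals=40)
        geno = simulate_genotypes(cfg, seed=9)
        assert (geno.variants["maf_observed"] >= 0.05).all()
        for _, sub in geno.variants.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
            assert sub["pos"].is_unique

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            _cfg(maf_range=(0.01, 0.5))

    def test_every_gene_has_configured_cis_variant_count(self):
        cfg = _cfg()
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes, seed=2)
        for g in genes:
            assert len(cis_variant_ids(g, geno)) == cfg.variants_per_gene

    def test_ld_blocks_produce_correlated_variants(self):
        cfg = _cfg(ld_block_size=4, ld_mutation_p=0.02, n_individuals=400)
        geno = simulate_genotypes(cfg, seed=4)
        X = geno.dosages[:, :4].astype(float)
        r2 = np.corrcoef(X.T) ** 2
        off = r2[np.triu_indices(4, 1)]
        assert off.mean() > 0.5


class TestExpressionPanel:
    def test_no_effects_no_cis_correlation_beyond_null_envelope(self):
        cfg = SimConfig(n_individuals=100, n_tissues=1, n_lnc=50, n_mrna=1,
                        variants_per_gene=5, frac_elnc=0.0, theta=0.0,
                        n_causal_pairs=1, confounder_sd=0.0, seed=13)
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes, seed=21)
        panel, _ = simulate_expression_panel(geno, genes, cfg, seed=22)
        tis = next(iter(panel.tissues.values()))
        rng = np.random.default_rng(0)

        def median_max_abs_r(expr_rows):
            out = []
            for g in genes:
                if g.is_coding:
                    continue
                y = expr_rows[g.gene_id]
                rs = [abs(np.corrcoef(geno.dosage(v), y)[0, 1])
                      for v in cis_variant_ids(g, geno)]
                out.append(max(rs))
            return float(np.median(out))

        obs_rows = {g: tis.matrix.loc[g].to_numpy(float) for g in panel.gene_ids}
        observed = median_max_abs_r(obs_rows)
        # permutation envelope: shuffle samples within each gene row
        perm_stats = []
        for _ in range(30):
            perm_rows = {g: rng.permutation(v) for g, v in obs_rows.items()}
            perm_stats.append(median_max_abs_r(perm_rows))
        assert observed <= np.quantile(perm_stats, 0.95) + 0.02

    def test_full_sharing_gives_identical_effects_across_tissues(self):
        cfg = _cfg(tissue_share_r=1.0, frac_elnc=1.0, n_tissues=4)
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes, seed=1)
        _, truth = simulate_expression_panel(geno, genes, cfg, seed=2)
        by_pair = {}
        for (g, v, t), b in truth.true_effects.items():
            by_pair.setdefault((g, v), []).append(b)
        for betas in by_pair.values():
            assert len(betas) == 4
            assert np.ptp(betas) < 1e-12

    def test_causal_pair_count_and_theta(self):
        cfg = _cfg(n_causal_pairs=3, theta=0.7)
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes, seed=1)
        _, truth = simulate_expression_panel(geno, genes, cfg, seed=2)
        assert len(truth.causal_pairs) == 3
        assert all(th == 0.7 for th in truth.causal_pairs.values())

    def test_true_effects_recoverable_by_ols_in_noise_free_limit(self):
        cfg = _cfg(noise_sd=1e-8, confounder_sd=0.0, frac_elnc=1.0, n_tissues=1)
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes, seed=1)
        panel, truth = simulate_expression_panel(geno, genes, cfg, seed=2)
        tis = next(iter(panel.tissues.values()))
        age = panel.covariates["age"].to_numpy()
        sex = panel.covariates["sex"].to_numpy()
        for (g, v, _t), beta in truth.true_effects.items():
            y = tis.matrix.loc[g].to_numpy(float)
            X = np.column_stack([np.ones_like(y), age, sex, geno.dosage(v)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert abs(coef[-1] - beta) / abs(beta) < 1e-6

    def test_determinism(self):
        cfg = _cfg()
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes, seed=1)
        p1, t1 = simulate_expression_panel(geno, genes, cfg, seed=5)
        p2, t2 = simulate_expression_panel(geno, genes, cfg, seed=5)
        for tid in p1.tissues:
            assert p1.tissues[tid].matrix.equals(p2.tissues[tid].matrix)
        assert t1.true_effects == t2.true_effects

    def test_too_many_causal_pairs_rejected(self):
        with pytest.raises(ValueError, match="n_causal_pairs"):
            _cfg(n_causal_pairs=1000)


class TestAnnotationBundle:
    def test_null_odds_ratio_calibration(self):
        # OR=1: the mean empirical cross-product OR over many draws of one
        # disease set stays within +-0.1 of 1 (cell counts kept large)
        cfg = SimConfig(n_individuals=40, n_tissues=1, n_lnc=100, n_mrna=1,
                        variants_per_gene=10, frac_elnc=1.0, n_causal_pairs=1,
                        n_diseases=1, disease_or=1.0, disease_base_rate=0.4,
                        peak_fraction=0.0, seed=3)
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes, seed=1)
        _, truth = simulate_expression_panel(geno, genes, cfg, seed=2)
        vids = geno.variants["variant_id"].to_numpy()
        is_true = np.isin(vids, sorted(truth.effect_variants()))
        ors = []
        for s in range(500):
            bundle = simulate_annotation_bundle(genes, geno, truth, cfg, seed=1000 + s)
            member = np.isin(vids, sorted(bundle.disease_sets["disease00"]))
            a = int((member & is_true).sum())
            b = int((~member & is_true).sum())
            c = int((member & ~is_true).sum())
            d = int((~member & ~is_true).sum())
            ors.append((a * d) / (b * c))
        assert abs(np.mean(ors) - 1.0) < 0.1

    def test_zero_peak_fraction_gives_empty_peaks(self, small_world, small_cfg):
        genes, geno, _, truth = small_world
        cfg = with_overrides(small_cfg, peak_fraction=0.0)
        bundle = simulate_annotation_bundle(genes, geno, truth, cfg, seed=1)
        assert bundle.tf_peaks == {}

    def test_determinism(self, small_world, small_cfg):
        genes, geno, _, truth = small_world
        b1 = simulate_annotation_bundle(genes, geno, truth, small_cfg, seed=8)
        b2 = simulate_annotation_bundle(genes, geno, truth, small_cfg, seed=8)
        assert b1.disease_sets == b2.disease_sets
        assert set(b1.tf_peaks) == set(b2.tf_peaks)
        for tf in b1.tf_peaks:
            assert b1.tf_peaks[tf].equals(b2.tf_peaks[tf])

    def test_negative_odds_ratio_rejected(self, small_world, small_cfg):
        genes, geno, _, truth = small_world
        with pytest.raises(ValueError, match="disease_or"):
            with_overrides(small_cfg, disease_or=-1.0)


class TestGwasSummary:
    def test_null_trait_z_scores_standard_normal(self, small_world, small_cfg):
        genes, geno, _, truth = small_world
        cohort = resample_genotypes(geno, 4000, seed=31)
        gwas = simulate_gwas_summary(cohort, truth, small_cfg, seed=32, trait_effects=None)
        _, p = sps.kstest(gwas.table["z"], "norm")
        assert p > 0.01

    def test_dominant_variant_attains_max_abs_z(self, small_world, small_cfg):
        genes, geno, panel, truth = small_world
        cohort = resample_genotypes(geno, 3000, seed=41)
        # a single lncRNA with one strong cis effect mediates half the trait
        (g, v, _t), beta = next(iter(truth.true_effects.items()))
        var_g = np.var(cohort.dosage(v)) * np.mean(beta) ** 2
        theta = np.sqrt(1.0 / var_g)  # genetic term variance ~ trait noise variance
        gwas = simulate_gwas_summary(cohort, truth, small_cfg, seed=42,
                                     trait_effects={g: float(theta)})
        top = gwas.table.loc[gwas.table["z"].abs().idxmax(), "variant_id"]
        assert top == v

    def test_z_equals_beta_over_se_and_determinism(self, small_world, small_cfg):
        genes, geno, _, truth = small_world
        cohort = resample_genotypes(geno, 500, seed=51)
        g1 = simulate_gwas_summary(cohort, truth, small_cfg, seed=52)
        g2 = simulate_gwas_summary(cohort, truth, small_cfg, seed=52)
        assert g1.table.equals(g2.table)
        assert np.allclose(g1.table["z"], g1.table["beta"] / g1.table["se"])

    def test_small_cohort_rejected(self, small_world, small_cfg):
        genes, geno, _, truth = small_world
        tiny = resample_genotypes(geno, 10, seed=6)
        with pytest.raises(ValueError, match="30"):
            simulate_gwas_summary(tiny, truth, small_cfg, seed=1)
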