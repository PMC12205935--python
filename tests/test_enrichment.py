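"""Exact 2x2 machinery, LD utilities, variant classes, MAF bins, disease scan."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from lnceqtl.enrichment import (
    classify_variant,
    disease_scan,
    fisher_enrichment,
    ld_filter,
    maf_bin_analysis,
    tss_distance_profile,
    variants_in_peaks,
)
from lnceqtl.types import EqtlCalls, GeneModel, GenotypeMatrix


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exhaustive two-sided exact p: sum over all tables with the observed
    margins whose point probability is <= the observed one (exact rational
    arithmetic, ties included)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


def _geno(dosages, positions=None, chrom=None, mafs=None) -> GenotypeMatrix:
    n, m = dosages.shape
    af = dosages.mean(axis=0) / 2
    var = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else "chr1",
        "pos": positions if positions is not None else (np.arange(m) + 1) * 1000,
        "maf_observed": mafs if mafs is not None else np.minimum(af, 1 - af),
    })
    return GenotypeMatrix(dosages, var, [f"s{i}" for i in range(n)])


class TestFisher:
    def test_strong_table_or_and_oracle_p(self):
        res = fisher_enrichment(8, 2, 1, 9)
        assert res.or_estimate == pytest.approx(36.0)
        assert res.p == pytest.approx(fisher_two_sided_oracle(8, 2, 1, 9), rel=1e-9)

    def test_proportional_table_or_is_one(self):
        assert fisher_enrichment(5, 5, 50, 50).or_estimate == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = fisher_enrichment(10, 0, 5, 5)
        assert res.or_estimate == pytest.approx(21.0)
        assert res.p == pytest.approx(fisher_two_sided_oracle(10, 0, 5, 5), rel=1e-9)

    def test_ci_brackets_or(self):
        res = fisher_enrichment(8, 2, 1, 9)
        assert res.ci_low <= res.or_estimate <= res.ci_high

    def test_exhaustive_sweep_small_margins(self):
        # every table with both margins <= 12 matches the enumeration oracle
        for r1 in range(1, 13):
            for r2 in range(1, 13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        p = fisher_enrichment(a, r1 - a, c, r2 - c).p
                        exp = fisher_two_sided_oracle(a, r1 - a, c, r2 - c)
                        assert p == pytest.approx(exp, rel=1e-7, abs=1e-12), (a, r1, c, r2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_enrichment(0, 0, 3, 4)


class TestLdFilter:
    def test_duplicate_columns_keep_first_by_position(self, rng):
        g = rng.integers(0, 3, 50).astype(np.int8)
        geno = _geno(np.column_stack([g, g, rng.integers(0, 3, 50)]))
        kept = ld_filter(geno, {"v0", "v1", "v2"}, mode="prune")
        assert "v0" in kept and "v1" not in kept

    def test_independent_columns_mostly_retained(self, rng):
        dos = rng.binomial(2, 0.4, size=(500, 40)).astype(np.int8)
        geno = _geno(dos)
        from lnceqtl.enrichment import _r2_matrix
        r2 = _r2_matrix(dos - dos.mean(axis=0))
        off = r2[np.triu_indices(40, 1)]
        assert off.mean() < 0.01
        kept = ld_filter(geno, set(geno.variants["variant_id"]), mode="prune")
        assert len(kept) == 40

    def test_prune_idempotent_and_exhaustively_valid(self, rng):
        dos = rng.binomial(2, 0.3, size=(80, 60)).astype(np.int8)
        for j in range(0, 60, 7):  # plant LD
            dos[:, j + 1] = dos[:, j]
        geno = _geno(dos)
        kept = ld_filter(geno, set(geno.variants["variant_id"]), mode="prune")
        again = ld_filter(geno, kept, mode="prune")
        assert again == kept
        idx = sorted(int(v[1:]) for v in kept)
        for i in idx:
            for j in idx:
                if i < j:
                    r = np.corrcoef(dos[:, i].astype(float), dos[:, j].astype(float))[0, 1]
                    assert r**2 <= 0.8

    def test_expand_returns_ld_partners_plus_index(self, rng):
        g = rng.integers(0, 3, 100).astype(np.int8)
        noise = rng.integers(0, 3, (100, 2)).astype(np.int8)
        geno = _geno(np.column_stack([g, g, noise]))
        got = ld_filter(geno, {"v1", "v2", "v3"}, mode="expand", index_set={"v0"})
        assert got == {"v0", "v1"}

    def test_absent_variant_named_in_error(self, small_world):
        _, geno, _, _ = small_world
        with pytest.raises(KeyError, match="nope"):
            ld_filter(geno, {"nope"}, mode="prune")


def _toy_genes() -> list[GeneModel]:
    # + strand coding gene with CDS [1200, 2800] inside exons
    coding = GeneModel("pc1", "protein_coding", "chr1", "+", 1000,
                       [(1000, 1500), (2000, 3000)], cds=(1200, 2800))
    linc = GeneModel("lnc1", "lincRNA", "chr1", "+", 10_000,
                     [(10_000, 10_500), (11_000, 12_000)])
    minus = GeneModel("pc2", "protein_coding", "chr2", "-", 9000,
                      [(5000, 9000)], cds=(6000, 8000))
    return [coding, linc, minus]


def _variants(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("chr1", 10_200, "ncRNA_exonic"),     # lncRNA exon
            ("chr1", 1502, "splicing"),            # 2 bp into a coding intron
            ("chr1", 1600, "intronic"),            # mid coding intron
            ("chr1", 1100, "UTR5"),                # exon before CDS on + strand
            ("chr1", 2900, "UTR3"),                # exon after CDS on + strand
            ("chr1", 2500, "exonic"),              # inside CDS
            ("chr1", 900, "upstream"),             # within 1 kb of + TSS
            ("chr1", 3500, "downstream"),
            ("chr2", 8500, "UTR5"),                # - strand: 5' end at high coords
            ("chr2", 5500, "UTR3"),
            ("chr2", 9500, "upstream"),            # - strand upstream is beyond end
            ("chr1", 500_000, "intergenic"),
            ("chrX", 100, "intergenic"),           # chromosome absent from models
            ("chr1", 10_700, "ncRNA_intronic"),
        ],
    )
    def test_rule_table(self, chrom, pos, expected):
        out = classify_variant(_variants([("v", chrom, pos)]), _toy_genes())
        assert out.iloc[0]["functional_class"] == expected

    def test_partition_and_oracle_on_random_variants(self, rng):
        genes = _toy_genes()
        rows = [(f"v{i}", rng.choice(["chr1", "chr2"]), int(rng.integers(1, 15_000)))
                for i in range(50)]
        out = classify_variant(_variants(rows), genes)
        assert len(out) == 50  # partition: every variant classified once

        # independent rule-check oracle: first matching rule in precedence order
        def oracle(chrom, pos):
            cand = set()
            for g in genes:
                if g.chrom != chrom:
                    continue
                exons = g.exons
                introns = [(e1 + 1, s2 - 1) for (s1, e1), (s2, e2) in zip(exons, exons[1:])]
                in_exon = any(s <= pos <= e for s, e in exons)
                in_intron = any(s <= pos <= e for s, e in introns)
                near_edge = any(
                    s <= pos <= min(s + 1, e) or max(e - 1, s) <= pos <= e
                    for s, e in introns
                )
                if g.biotype == "protein_coding":
                    if in_intron and near_edge:
                        cand.add("splicing")
                    if in_exon:
                        cs, ce = g.cds
                        if cs <= pos <= ce:
                            cand.add("exonic")
                        elif (pos < cs) == (g.strand == "+"):
                            cand.add("UTR5")
                        else:
                            cand.add("UTR3")
                    if in_intron:
                        cand.add("intronic")
                else:
                    if in_intron and near_edge:
                        cand.add("ncRNA_splicing")
                    if in_exon:
                        cand.add("ncRNA_exonic")
                    if in_intron:
                        cand.add("ncRNA_intronic")
                five, three = (g.exons[0][0], g.exons[-1][1])
                up_zone = (five - 1000 <= pos < five) if g.strand == "+" else (three < pos <= three + 1000)
                down_zone = (three < pos <= three + 1000) if g.strand == "+" else (five - 1000 <= pos < five)
                if up_zone:
                    cand.add("upstream")
                if down_zone:
                    cand.add("downstream")
            order = ["splicing", "exonic", "UTR5", "UTR3", "ncRNA_splicing",
                     "ncRNA_exonic", "intronic", "ncRNA_intronic", "upstream",
                     "downstream", "intergenic"]
            for cls in order:
                if cls in cand:
                    return cls
            return "intergenic"

        for (vid, chrom, pos), got in zip(rows, out["functional_class"]):
            assert got == oracle(chrom, pos), (chrom, pos)


class TestMafBins:
    def _geno_with_mafs(self, mafs):
        m = len(mafs)
        dos = np.zeros((4, m), dtype=np.int8)
        dos[0] = 1
        return _geno(dos, mafs=np.asarray(mafs))

    def test_constructed_opposite_densities_give_positive_trend(self, rng):
        # eSNP MAF density ~ maf, non-eSNP density ~ (1 - maf)
        maf_e = 0.05 + 0.45 * np.sqrt(rng.random(3000))
        maf_n = 0.05 + 0.45 * (1 - np.sqrt(rng.random(3000)))
        geno = self._geno_with_mafs(np.concatenate([maf_e, maf_n]))
        esnps = {f"v{j}" for j in range(3000)}
        non = {f"v{j}" for j in range(3000, 6000)}
        res = maf_bin_analysis(esnps, non, geno)
        assert res.trend_slope > 0
        ors = res.bins["OR"].to_numpy()
        assert ors[-1] > 1 > ors[0]
        assert np.all(np.diff(ors) > 0)

    def test_identical_distributions_trend_not_significant(self, rng):
        maf = 0.05 + 0.45 * rng.random(4000)
        geno = self._geno_with_mafs(maf)
        esnps = {f"v{j}" for j in range(2000)}
        non = {f"v{j}" for j in range(2000, 4000)}
        res = maf_bin_analysis(esnps, non, geno)
        assert res.trend_p > 0.01

    def test_proportions_sum_to_one_over_bins(self, rng):
        maf = 0.05 + 0.45 * rng.random(500)
        geno = self._geno_with_mafs(maf)
        res = maf_bin_analysis({f"v{j}" for j in range(250)},
                               {f"v{j}" for j in range(250, 500)}, geno)
        assert res.bins["esnp_prop"].sum() == pytest.approx(1.0)
        assert res.bins["non_esnp_prop"].sum() == pytest.approx(1.0)

    def test_sub_qc_maf_rejected(self):
        geno = self._geno_with_mafs([0.03, 0.2])
        with pytest.raises(ValueError, match="QC"):
            maf_bin_analysis({"v0"}, {"v1"}, geno)


class TestDiseaseScan:
    def test_null_fdr_calibration(self):
        # random disease sets with no enrichment: mean fraction q<0.05 <= 0.05
        fracs = []
        for rep in range(20):
            rng = np.random.default_rng(700 + rep)
            dos = rng.binomial(2, 0.3, size=(60, 400)).astype(np.int8)
            geno = _geno(dos)
            vids = list(geno.variants["variant_id"])
            esnps = set(rng.choice(vids, 80, replace=False))
            non = set(rng.choice(sorted(set(vids) - esnps), 200, replace=False))
            sets = {f"d{k}": set(rng.choice(vids, 30, replace=False)) for k in range(50)}
            res = disease_scan(esnps, non, sets, geno)
            fracs.append(np.mean([r.q < 0.05 for r in res]))
        assert np.mean(fracs) <= 0.05

    def test_planted_disease_set_inside_esnps_is_top_hit(self, rng):
        dos = rng.binomial(2, 0.3, size=(60, 300)).astype(np.int8)
        geno = _geno(dos)
        vids = list(geno.variants["variant_id"])
        esnps = set(vids[:60])
        non = set(vids[60:260])
        sets = {"planted": set(list(esnps)[:30])}
        sets.update({f"d{k}": set(rng.choice(vids, 30, replace=False)) for k in range(10)})
        res = disease_scan(esnps, non, sets, geno)
        by_label = {r.label: r for r in res}
        assert by_label["planted"].or_estimate > 1
        assert by_label["planted"].q == min(r.q for r in res)

    def test_unresolvable_disease_skipped(self, rng, caplog):
        dos = rng.binomial(2, 0.3, size=(30, 50)).astype(np.int8)
        geno = _geno(dos)
        vids = list(geno.variants["variant_id"])
        res = disease_scan(set(vids[:10]), set(vids[10:30]),
                           {"ghost": {"absent1", "absent2"}}, geno)
        assert res == []


class TestTssProfile:
    def _calls(self, esnps_by_gene):
        genes = pd.DataFrame({"gene": list(esnps_by_gene), "min_p_obs": 0.0,
                              "empirical_p": 0.005, "q": 0.001, "is_elncRNA": True,
                              "esnp_threshold": 0.01})
        return EqtlCalls(genes, esnps_by_gene)

    def test_all_esnps_at_tss_land_in_zero_bin(self):
        g = GeneModel("g0", "lincRNA", "chr1", "+", 2_000_000, [(2_000_000, 2_001_000)])
        dos = np.tile(np.array([[0, 1, 2, 1]], dtype=np.int8).T, (1, 1))
        geno = _geno(dos, positions=[2_000_000])
        prof = tss_distance_profile(self._calls({"g0": {"v0"}}), [g], geno=geno)
        assert len(prof) == 1
        assert prof.iloc[0]["percentage"] == pytest.approx(100.0)
        assert prof.iloc[0]["bin_low"] <= 0 < prof.iloc[0]["bin_high"]

    def test_negative_strand_flips_sign(self):
        gplus = GeneModel("gp", "lincRNA", "chr1", "+", 1_000_000, [(1_000_000, 1_001_000)])
        gminus = GeneModel("gm", "lincRNA", "chr2", "-", 1_000_000, [(999_000, 1_000_000)])
        dos = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
        geno = _geno(dos, positions=[1_005_000, 1_005_000], chrom=["chr1", "chr2"])
        p_plus = tss_distance_profile(self._calls({"gp": {"v0"}}), [gplus], geno=geno)
        p_minus = tss_distance_profile(self._calls({"gm": {"v1"}}), [gminus], geno=geno)
        assert p_plus.iloc[0]["bin_low"] == 0
        assert p_minus.iloc[0]["bin_high"] == 0  # 5 kb 3' of a - TSS: upstream bin

    def test_uniform_esnps_percentages_sum_and_spread(self, rng):
        g = GeneModel("g0", "lincRNA", "chr1", "+", 1_100_000, [(1_100_000, 1_101_000)])
        m = 400
        pos = np.sort(rng.integers(100_000, 2_100_000, size=m))
        dos = rng.binomial(2, 0.3, size=(10, m)).astype(np.int8)
        geno = _geno(dos, positions=pos)
        prof = tss_distance_profile(
            self._calls({"g0": set(geno.variants["variant_id"])}), [g], geno=geno
        )
        assert prof["percentage"].sum() == pytest.approx(100.0, abs=1e-9)
        # uniform placement: the largest 10-kb bin share stays near uniform
        n_bins = len(prof)
        assert prof["percentage"].max() < 100.0 / n_bins * 3


class TestPeakMembership:
    def test_interval_membership_inclusive(self):
        dos = np.array([[0, 1, 2]], dtype=np.int8).repeat(4, axis=0)
        geno = _geno(dos, positions=[100, 200, 300])
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [200]})
        assert variants_in_peaks(geno, peaks) == {"v1"}
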