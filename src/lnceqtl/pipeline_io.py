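"""File formats, run configuration, and end-to-end orchestration.

On-disk formats: dosage/variant/expression/GWAS/disease TSV, BED gene
models and peaks (0-based half-open on disk, 1-based inclusive in memory),
VCF genotypes (via cyvcf2), GMT gene sets, JSON provenance. Writers and
readers are inverse pairs for their schema. TSVs use '.' for missing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causal as causal_mod
from . import cis_eqtl, enrichment, preprocess, regional, synthgen, twas
from .synthgen import CovariateSpec, SimConfig
from .types import (
    AnnotationBundle,
    CovariateMatrix,
    EqtlCalls,
    EqtlTable,
    ExpressionPanel,
    GeneModel,
    GenotypeMatrix,
    GwasSummary,
    TissueExpression,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# writers


def _write_tsv(frame: pd.DataFrame, path: Path, header_lines: list[str] | None = None,
               index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, na_rep=".", float_format="%.6g")


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["."], **kw)


def write_genotypes(geno: GenotypeMatrix, prefix: Path) -> None:
    dos = pd.DataFrame(geno.dosages.T, columns=geno.samples)
    dos.insert(0, "variant_id", geno.variants["variant_id"].to_numpy())
    _write_tsv(dos, prefix.with_suffix(".dosage.tsv"))
    _write_tsv(geno.variants, prefix.with_suffix(".variants.tsv"))


def read_genotypes(prefix: Path) -> GenotypeMatrix:
    dos = _read_tsv(prefix.with_suffix(".dosage.tsv"))
    var = _read_tsv(prefix.with_suffix(".variants.tsv"))
    samples = [c for c in dos.columns if c != "variant_id"]
    mat = dos[samples].to_numpy(float).T
    if np.isnan(mat).any():
        miss = np.isnan(mat).mean(axis=0)
        logger.info("mean-imputing %d dosage entries", int(np.isnan(mat).sum()))
        mu = np.nanmean(mat, axis=0)
        ii = np.where(np.isnan(mat))
        mat[ii] = mu[ii[1]]
        var = var.copy()
        var["missingness"] = miss
    return GenotypeMatrix(mat, var, samples)


def read_vcf(path: Path) -> GenotypeMatrix:
    """Biallelic GT dosages from a VCF; missing genotypes mean-imputed with
    a per-variant missingness report."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, recs = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"non-biallelic record at {rec.CHROM}:{rec.POS}")
        gts = np.array([a + b if a >= 0 and b >= 0 else np.nan
                        for a, b, *_ in rec.genotypes], dtype=float)
        rows.append(gts)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        recs.append((vid, rec.CHROM, rec.POS))
    mat = np.array(rows).T if rows else np.empty((len(samples), 0))
    miss = np.isnan(mat).mean(axis=0) if rows else np.array([])
    if rows and np.isnan(mat).any():
        mu = np.nanmean(mat, axis=0)
        ii = np.where(np.isnan(mat))
        mat[ii] = mu[ii[1]]
    var = pd.DataFrame(recs, columns=["variant_id", "chrom", "pos"])
    af = mat.mean(axis=0) / 2.0 if rows else np.array([])
    var["maf_observed"] = np.minimum(af, 1 - af)
    var["missingness"] = miss
    return GenotypeMatrix(mat, var, samples)


def write_gene_models(genes: list[GeneModel], path: Path) -> None:
    """BED on disk: 0-based half-open span, name, score 0, strand, plus
    biotype and (for coding genes) a 0-based half-open CDS interval."""
    rows = []
    for g in genes:
        cds_s = g.cds[0] - 1 if g.cds else "."
        cds_e = g.cds[1] if g.cds else "."
        rows.append((g.chrom, g.start - 1, g.end, g.gene_id, 0, g.strand, g.biotype, cds_s, cds_e))
    frame = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "biotype", "cds_start", "cds_end"],
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, header=False)


def read_gene_models(path: Path) -> list[GeneModel]:
    """BED (>= 6 columns) to gene models: disk interval [start, end) becomes
    1-based inclusive [start+1, end]; TSS is the interval start on '+' and
    the interval end on '-'. Optional columns 7-9 carry biotype and CDS."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BED record needs >= 6 columns")
            chrom, s0, e0, name, _score, strand = f[:6]
            start, end = int(s0) + 1, int(e0)
            biotype = f[6] if len(f) > 6 and f[6] != "." else "lincRNA"
            cds = None
            if len(f) > 8 and f[7] != "." and f[8] != ".":
                cds = (int(f[7]) + 1, int(f[8]))
            tss = start if strand == "+" else end
            genes.append(GeneModel(name, biotype, chrom, strand, tss, [(start, end)], cds))
    return genes


def write_expression_panel(panel: ExpressionPanel, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for tid, tis in panel.tissues.items():
        _write_tsv(tis.matrix, outdir / f"expr_{tid}.tsv", index=True)
        smap = pd.DataFrame({"sample": tis.samples, "donor": tis.donors})
        _write_tsv(smap, outdir / f"samples_{tid}.tsv")
    cov = panel.covariates.copy()
    cov.index.name = "donor"
    _write_tsv(cov, outdir / "covariates.tsv", index=True)


def read_expression_panel(outdir: Path) -> ExpressionPanel:
    outdir = Path(outdir)
    cov = _read_tsv(outdir / "covariates.tsv", index_col=0)
    tissues = {}
    gene_ids = None
    for f in sorted(outdir.glob("expr_*.tsv")):
        tid = f.stem.removeprefix("expr_")
        mat = _read_tsv(f, index_col=0)
        smap = _read_tsv(outdir / f"samples_{tid}.tsv")
        tissues[tid] = TissueExpression(tid, mat, dict(zip(smap["sample"], smap["donor"])))
        gene_ids = list(mat.index)
    if not tissues:
        raise ValueError(f"no expression matrices under {outdir}")
    return ExpressionPanel(tissues, gene_ids, cov)


def write_gwas(gwas: GwasSummary, path: Path) -> None:
    _write_tsv(gwas.table, path)


def read_gwas(path: Path) -> GwasSummary:
    t = _read_tsv(path)
    if "z" not in t.columns:
        if {"beta", "se"} <= set(t.columns):
            t["z"] = t["beta"] / t["se"]
        else:
            raise ValueError(f"{path}: need a 'z' column or 'beta' + 'se'")
    for col in ("beta", "se"):
        if col not in t.columns:
            t[col] = np.nan
    if "n" not in t.columns:
        t["n"] = np.nan
    return GwasSummary(t[["variant_id", "z", "beta", "se", "n"]])


def write_disease_sets(sets: dict[str, set[str]], path: Path) -> None:
    rows = [(d, v) for d, vs in sets.items() for v in sorted(vs)]
    _write_tsv(pd.DataFrame(rows, columns=["disease", "variant_id"]), path)


def read_disease_sets(path: Path) -> dict[str, set[str]]:
    t = _read_tsv(path)
    return {d: set(sub["variant_id"]) for d, sub in t.groupby("disease")}


def write_peaks(peaks: dict[str, pd.DataFrame], path: Path) -> None:
    rows = []
    for tf, frame in peaks.items():
        for _, r in frame.iterrows():
            rows.append((r["chrom"], int(r["start"]) - 1, int(r["end"]), tf))
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_peaks(path: Path) -> dict[str, pd.DataFrame]:
    t = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    t["start"] = t["start"] + 1
    return {tf: sub[["chrom", "start", "end"]].reset_index(drop=True)
            for tf, sub in t.groupby("name")}


def read_gmt(path: Path) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = set(f[2:])
    return sets


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    mode: str = "synthetic"
    sim: SimConfig = field(default_factory=SimConfig)
    paths: dict = field(default_factory=dict)  # real mode input paths
    stages: dict = field(
        default_factory=lambda: {
            "preprocess": True,
            "cis_eqtl": True,
            "enrichment": True,
            "regional": True,
            "twas": True,
            "causal": True,
        }
    )
    window: int = 1_000_000
    q_level: float = 0.05
    n_perm: int = 1000
    r2: float = 0.8
    maf_floor: float = 0.05
    fc_threshold: float = 1.5
    n_genotype_pcs: int = 3
    elnc_rule: str = "bh"
    seed: int = 17
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name in ("window", "q_level", "n_perm", "r2", "maf_floor", "fc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode == "real":
            needed = {"genotypes", "expression", "gene_models"}
            missing = needed - set(self.paths)
            if missing:
                raise ValueError(f"real mode requires paths: {sorted(missing)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            cspec = sim.get("covariate_spec", {})
            if isinstance(cspec, dict):
                cspec = dict(cspec)
                if "age_range" in cspec:
                    cspec["age_range"] = tuple(cspec["age_range"])
                sim["covariate_spec"] = CovariateSpec(**cspec)
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            d["sim"] = SimConfig(**sim)
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(cfg.to_dict(), default=list)), fh)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ResultBundle:
    config_hash: str
    seed: int
    genes: list[GeneModel] = field(default_factory=list)
    geno: GenotypeMatrix | None = None
    panel: ExpressionPanel | None = None
    truth: object | None = None
    annotations: AnnotationBundle | None = None
    gwas: GwasSummary | None = None
    covariates: dict[str, CovariateMatrix] = field(default_factory=dict)
    eqtl_tables: dict[str, EqtlTable] = field(default_factory=dict)
    calls: dict[str, EqtlCalls] = field(default_factory=dict)
    non_esnps: set = field(default_factory=set)
    enrichment_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    regional_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    twas_models: list = field(default_factory=list)
    twas_table: pd.DataFrame | None = None
    causal_estimates: list = field(default_factory=list)


def read_inputs(cfg: RunConfig):
    """Load (or synthesize) the pipeline inputs for a RunConfig."""
    if cfg.mode == "synthetic":
        sim = cfg.sim
        genes = synthgen.simulate_gene_models(sim)
        geno = synthgen.simulate_genotypes(sim, genes, seed=cfg.seed)
        panel, truth = synthgen.simulate_expression_panel(geno, genes, sim, seed=cfg.seed + 1)
        ann = synthgen.simulate_annotation_bundle(genes, geno, truth, sim, seed=cfg.seed + 2)
        cohort = synthgen.resample_genotypes(geno, sim.gwas_n, seed=cfg.seed + 3)
        trait = {l: sim.theta for (l, _m) in truth.causal_pairs}
        gwas = synthgen.simulate_gwas_summary(cohort, truth, sim, seed=cfg.seed + 4, trait_effects=trait)
        return genes, geno, panel, truth, ann, gwas, cohort
    p = {k: Path(v) for k, v in cfg.paths.items()}
    gpath = p["genotypes"]
    geno = read_vcf(gpath) if gpath.suffix == ".vcf" else read_genotypes(gpath)
    genes = read_gene_models(p["gene_models"])
    panel = read_expression_panel(p["expression"])
    # enforce sample alignment by donor-id intersection
    donors = set(geno.samples)
    for tis in panel.tissues.values():
        extra = set(tis.donors) - donors
        if set(tis.donors) & donors == set():
            raise ValueError("sample intersection between genotypes and expression is empty")
        if extra:
            logger.warning("tissue %s: %d samples without genotypes dropped", tis.tissue_id, len(extra))
            keep = [s for s in tis.samples if tis.donor_map[s] in donors]
            tis.matrix = tis.matrix[keep]
            tis.donor_map = {s: tis.donor_map[s] for s in keep}
    gwas = read_gwas(p["gwas"]) if "gwas" in p else None
    ann = None
    if "disease_sets" in p:
        ann = AnnotationBundle(
            pd.DataFrame(columns=["chrom", "start", "end", "label"]),
            read_peaks(p["peaks"]) if "peaks" in p else {},
            read_disease_sets(p["disease_sets"]),
        )
    return genes, geno, panel, None, ann, gwas, geno


def write_synthetic_inputs(cfg: RunConfig, outdir: Path) -> None:
    """Materialize a synthetic bundle in the on-disk formats real mode reads."""
    genes, geno, panel, truth, ann, gwas, _ = read_inputs(cfg)
    outdir = Path(outdir)
    write_genotypes(geno, outdir / "genotypes")
    write_gene_models(genes, outdir / "gene_models.bed")
    write_expression_panel(panel, outdir / "expression")
    if gwas is not None:
        write_gwas(gwas, outdir / "gwas.tsv")
    if ann is not None:
        write_disease_sets(ann.disease_sets, outdir / "disease_sets.tsv")
        write_peaks(ann.tf_peaks, outdir / "tf_peaks.bed")
    save_config(cfg, outdir / "config.yaml")


def _tissue_covariates(panel, geno, cfg) -> dict[str, CovariateMatrix]:
    """Known covariates + genotype PCs + hidden factors, per tissue."""
    k_pc = min(cfg.n_genotype_pcs, geno.n_individuals - 1, geno.n_variants)
    pcs = preprocess.compute_genotype_pcs(geno, k_pc)
    out = {}
    for tid, tis in panel.tissues.items():
        donors = tis.donors
        base = pd.DataFrame(
            {
                "age": panel.covariates.loc[donors, "age"].to_numpy(),
                "sex": panel.covariates.loc[donors, "sex"].to_numpy(),
            },
            index=tis.samples,
        )
        pc_block = pcs.data.loc[donors].set_index(base.index)
        known = CovariateMatrix(pd.concat([base, pc_block], axis=1))
        # also cap by gene count: with few genes, factors would absorb
        # per-gene signal rather than shared structure
        k_hf = preprocess.default_n_hidden_factors(len(donors))
        k_hf = min(k_hf, max(0, len(donors) - known.data.shape[1] - 2),
                   len(panel.gene_ids) // 10)
        if k_hf > 0:
            hf = preprocess.infer_hidden_factors(tis.matrix, known, k_hf)
            known = CovariateMatrix(pd.concat([known.data, hf.scores], axis=1))
        out[tid] = known
    return out


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Execute the enabled stages in dependency order on one RunConfig.

    Stage order: preprocess -> cis_eqtl -> {enrichment, regional} -> twas ->
    causal. A disabled prerequisite with no in-memory output raises an
    error naming the missing dependency. All stochastic steps derive their
    seeds from cfg.seed, so re-running the same config reproduces every
    table bit-identically.
    """
    t0 = time.time()
    genes, geno, panel, truth, ann, gwas, ld_cohort = read_inputs(cfg)
    bundle = ResultBundle(config_hash=cfg.config_hash(), seed=cfg.seed, genes=genes,
                          geno=geno, panel=panel, truth=truth, annotations=ann, gwas=gwas)
    stages = cfg.stages
    lnc_genes = [g for g in genes if not g.is_coding]

    def need(stage: str, for_stage: str):
        if not stages.get(stage, False):
            raise ValueError(f"stage '{for_stage}' requires disabled stage '{stage}'")

    if stages.get("preprocess", True):
        bundle.covariates = _tissue_covariates(panel, geno, cfg)
        logger.info("preprocess: %d tissues, %.1fs", len(panel.tissues), time.time() - t0)

    if stages.get("cis_eqtl", True):
        need("preprocess", "cis_eqtl")
        pairs = cis_eqtl.enumerate_cis_pairs(lnc_genes, geno, cfg.window)
        for ti, (tid, tis) in enumerate(panel.tissues.items()):
            cov = bundle.covariates[tid]
            lnc_expr = tis.matrix.loc[[g.gene_id for g in lnc_genes]]
            tab = cis_eqtl.fit_nominal(lnc_expr, geno, cov, pairs, tis.donor_map)
            null = cis_eqtl.permute_min_p(
                lnc_expr, geno, cov, pairs, cfg.n_perm, seed=cfg.seed + 100 + ti,
                donor_map=tis.donor_map,
            )
            bundle.eqtl_tables[tid] = tab
            bundle.calls[tid] = cis_eqtl.call_signals(tab, null, cfg.q_level, cfg.elnc_rule)
        first = next(iter(bundle.eqtl_tables.values()))
        bundle.non_esnps = cis_eqtl.select_non_esnps(first, geno, r2=cfg.r2)
        n_elnc = len(set().union(*[c.elncrnas for c in bundle.calls.values()]))
        logger.info("cis_eqtl: %d pairs, %d elncRNAs across tissues, %.1fs",
                    len(pairs.pairs), n_elnc, time.time() - t0)

    esnp_by_tissue = {tid: c.all_esnps() for tid, c in bundle.calls.items()} if bundle.calls else {}
    esnp_union = set().union(*esnp_by_tissue.values()) if esnp_by_tissue else set()

    if stages.get("enrichment", True):
        need("cis_eqtl", "enrichment")
        ann_table = enrichment.classify_variant(geno.variants, genes)
        bundle.enrichment_tables["functional_classes"] = ann_table
        if esnp_union and bundle.non_esnps:
            func = enrichment.functional_enrichment(esnp_union, bundle.non_esnps, ann_table)
            bundle.enrichment_tables["functional"] = pd.DataFrame([r.as_dict() for r in func])
            if ann is not None and ann.tf_peaks:
                tf = enrichment.tf_peak_enrichment(esnp_union, bundle.non_esnps, ann.tf_peaks, geno)
                bundle.enrichment_tables["tf_peaks"] = pd.DataFrame([r.as_dict() for r in tf])
            mafres = enrichment.maf_bin_analysis(esnp_by_tissue, bundle.non_esnps, geno)
            bundle.enrichment_tables["maf_bins"] = mafres.bins
            if ann is not None and ann.disease_sets:
                dis = enrichment.disease_scan(
                    esnp_by_tissue, bundle.non_esnps, ann.disease_sets, geno, cfg.r2, cfg.q_level
                )
                bundle.enrichment_tables["disease"] = pd.DataFrame([r.as_dict() for r in dis])
            merged_calls = _merge_calls(bundle.calls)
            if merged_calls.esnps:
                bundle.enrichment_tables["tss_profile"] = enrichment.tss_distance_profile(
                    merged_calls, genes, geno=geno
                )

    if stages.get("regional", True):
        need("cis_eqtl", "regional")
        de = [regional.differential_expression(panel, tid, cfg.fc_threshold, cfg.q_level)
              for tid in panel.tissue_ids] if len(panel.tissues) >= 2 else []
        if de:
            bundle.regional_tables["de"] = pd.concat(de, ignore_index=True)
        elnc_sets = {tid: c.elncrnas for tid, c in bundle.calls.items()}
        if len(elnc_sets) >= 2:
            bundle.regional_tables["jaccard"] = regional.jaccard_matrix(elnc_sets)
        tids = panel.tissue_ids
        if len(tids) >= 2 and bundle.non_esnps:
            try:
                rb = regional.estimate_rb(
                    bundle.eqtl_tables[tids[0]], bundle.eqtl_tables[tids[1]], bundle.non_esnps
                )
                bundle.regional_tables["rb"] = pd.DataFrame(
                    [{"tissue_a": tids[0], "tissue_b": tids[1], "rb": rb.rb,
                      "se": rb.se, "r_e": rb.r_e, "n_pairs": rb.n_pairs}]
                )
            except ValueError as err:
                logger.warning("rb estimation skipped: %s", err)

    if stages.get("twas", True):
        need("preprocess", "twas")
        need("cis_eqtl", "twas")
        if gwas is None:
            logger.warning("twas stage skipped: no GWAS summary provided")
        else:
            tid = panel.tissue_ids[0]
            tis = panel.tissues[tid]
            cov = bundle.covariates[tid]
            resid = preprocess.residualize(tis.matrix, cov)
            gidx = {s: i for i, s in enumerate(geno.samples)}
            rows = [gidx[tis.donor_map[s]] for s in tis.samples]
            candidates = sorted(bundle.calls[tid].elncrnas) or [g.gene_id for g in lnc_genes]
            pairs = cis_eqtl.enumerate_cis_pairs(
                [g for g in lnc_genes if g.gene_id in set(candidates)], geno, cfg.window
            )
            for gene_id in candidates:
                cis = pairs.variants_of(gene_id)
                if len(cis) < 2:
                    continue
                m = twas.train_cis_weights(
                    resid.loc[gene_id].to_numpy(float), geno, cis, gene=gene_id,
                    seed=cfg.seed + 5, sample_rows=rows,
                )
                bundle.twas_models.append(m)
            bundle.twas_table = twas.twas_scan(bundle.twas_models, gwas, ld_cohort, tissue=tid)
            logger.info("twas: %d models, %d retained, %.1fs", len(bundle.twas_models),
                        sum(m.retained for m in bundle.twas_models), time.time() - t0)

    if stages.get("causal", True):
        need("twas", "causal")
        need("cis_eqtl", "causal")
        if bundle.twas_table is not None and len(bundle.twas_table):
            hits = sorted(bundle.twas_table.loc[bundle.twas_table["sig_p05"], "gene"])
            tid = panel.tissue_ids[0]
            merged = _merge_calls(bundle.calls)
            # 2SLS covariates: known covariates and genotype PCs only.
            # Expression-derived hidden factors are functions of the very
            # expression vectors being related, and conditioning on them
            # induces collider bias in the instrumented fit at small gene
            # counts.
            cov_full = bundle.covariates[tid]
            keep = [c for c in cov_full.names if not c.startswith("HF")]
            cov_known = CovariateMatrix(cov_full.data[keep])
            bundle.causal_estimates = causal_mod.causal_scan(
                hits,
                ExpressionPanel({tid: panel.tissues[tid]}, panel.gene_ids, panel.covariates),
                merged, geno, {tid: cov_known}, genes, q_level=cfg.q_level,
                r2=cfg.r2,
            )
            logger.info("causal: %d estimates, %.1fs", len(bundle.causal_estimates), time.time() - t0)

    return bundle


def _merge_calls(calls: dict[str, EqtlCalls]) -> EqtlCalls:
    """Union of per-tissue eSNP sets (a gene's eSNPs pooled over tissues)."""
    esnps: dict[str, set[str]] = {}
    frames = []
    for c in calls.values():
        frames.append(c.genes)
        for g, s in c.esnps.items():
            esnps.setdefault(g, set()).update(s)
    genes = pd.concat(frames, ignore_index=True).sort_values("q").drop_duplicates("gene")
    return EqtlCalls(genes.reset_index(drop=True), esnps)


def write_bundle(bundle: ResultBundle, outdir: Path, cfg: RunConfig) -> None:
    """Serialize every result table with provenance headers."""
    outdir = Path(outdir)
    hdr = [f"config_hash={bundle.config_hash}", f"seed={bundle.seed}", f"n_perm={cfg.n_perm}"]
    for tid, tab in bundle.eqtl_tables.items():
        _write_tsv(tab.table, outdir / f"eqtl_{tid}.tsv", hdr)
    for tid, c in bundle.calls.items():
        _write_tsv(c.genes, outdir / f"calls_{tid}.tsv", hdr)
    if bundle.non_esnps:
        _write_tsv(pd.DataFrame({"variant_id": sorted(bundle.non_esnps)}),
                   outdir / "non_esnps.tsv", hdr)
    for name, t in {**bundle.enrichment_tables, **bundle.regional_tables}.items():
        _write_tsv(t, outdir / f"{name}.tsv", hdr, index=(name == "jaccard"))
    if bundle.twas_table is not None:
        _write_tsv(bundle.twas_table, outdir / "twas.tsv", hdr)
    if bundle.causal_estimates:
        rows = [{
            "lnc": e.lnc, "mrna": e.mrna, "tissue": e.tissue, "beta_iv": e.beta_iv,
            "se": e.se, "p": e.p, "q": e.q, "first_stage_F": e.first_stage_F,
            "weak_instrument": e.weak_instrument,
            "n_instruments": len(e.instruments), "tss_distance": e.tss_distance,
        } for e in bundle.causal_estimates]
        _write_tsv(pd.DataFrame(rows), outdir / "causal.tsv", hdr)
    prov = {"config_hash": bundle.config_hash, "seed": bundle.seed,
            "config": json.loads(json.dumps(cfg.to_dict(), default=list))}
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))
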