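"""Cis-eQTL mapping with a permutation minimum-p null.

Nominal association is per-pair OLS of expression on dosage plus covariates;
the per-gene null is the distribution of the minimum nominal p across a
gene's cis variants under sample-label permutation of covariate-residualized
expression (one shared permutation per round, so per-gene minima are
comparable across genes). An lncRNA whose observed minimum beats the null
(BH q below the level) is an elncRNA; its eSNPs are the cis variants with
nominal p at or below the empirical 5th percentile of its permuted minima.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, floor_p
from .types import (
    CisPairIndex,
    CovariateMatrix,
    EqtlCalls,
    EqtlTable,
    GeneModel,
    GenotypeMatrix,
    PermNull,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000


def enumerate_cis_pairs(
    genes: list[GeneModel], geno: GenotypeMatrix, window: int = DEFAULT_WINDOW
) -> CisPairIndex:
    """All (gene, variant) pairs with the variant inside the inclusive
    window [tss - window, tss + window] on the gene's chromosome."""
    v = geno.variants
    rows = []
    empty = []
    for g in genes:
        m = (v["chrom"] == g.chrom) & ((v["pos"] - g.tss).abs() <= window)
        ids = v.loc[m, "variant_id"]
        if len(ids) == 0:
            empty.append(g.gene_id)
            continue
        rows.append(pd.DataFrame({"gene_id": g.gene_id, "variant_id": ids}))
    if empty:
        logger.warning("%d genes have no cis variants: %s...", len(empty), empty[:5])
    pairs = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["gene_id", "variant_id"])
    )
    return CisPairIndex(pairs, window, empty)


def _aligned_dosages(geno: GenotypeMatrix, sample_ids, donor_map=None) -> np.ndarray:
    donors = [donor_map[s] for s in sample_ids] if donor_map else list(sample_ids)
    idx = {s: i for i, s in enumerate(geno.samples)}
    rows = [idx[d] for d in donors]
    return geno.dosages[rows].astype(float)


def _prepare(expr, geno, covars, pairs, donor_map):
    """Residualize expression and dosages on covariates (Frisch-Waugh); the
    per-pair slope on the residualized data equals the full-model OLS slope."""
    genes = [g for g in pairs.gene_ids if g in set(expr.index)]
    n = expr.shape[1]
    X_all = _aligned_dosages(geno, expr.columns, donor_map)
    var_ids = list(dict.fromkeys(pairs.pairs["variant_id"]))
    col = {v: geno.column_index(v) for v in var_ids}
    if covars is not None and covars.data.shape[1] > 0:
        C = np.column_stack([np.ones(n), covars.values()])
        p_model = C.shape[1] + 1
    else:
        C = np.ones((n, 1))
        p_model = 2
    Q, _ = np.linalg.qr(C)

    def resid(M):
        return M - Q @ (Q.T @ M)

    Xr_full = resid(X_all[:, [col[v] for v in var_ids]])
    xr_index = {v: j for j, v in enumerate(var_ids)}
    const_mask = X_all[:, [col[v] for v in var_ids]].std(axis=0) == 0
    Yr = resid(expr.loc[genes].to_numpy(float).T)  # samples x genes
    return genes, var_ids, xr_index, const_mask, Xr_full, Yr, n, p_model


def fit_nominal(
    expr: pd.DataFrame,
    geno: GenotypeMatrix,
    covars: CovariateMatrix | None,
    pairs: CisPairIndex,
    donor_map: dict[str, str] | None = None,
) -> EqtlTable:
    """Per-pair OLS of expression on dosage + covariates + intercept with a
    two-sided t-test on the dosage slope (df = n - p).

    ``expr`` is genes x samples; samples map onto genotype rows directly by
    id, or through ``donor_map`` when expression sample ids are
    tissue-specific. Pairs whose dosage is constant are skipped and logged.
    """
    genes, var_ids, xr_index, const_mask, Xr, Yr, n, p_model = _prepare(
        expr, geno, covars, pairs, donor_map
    )
    df = n - p_model
    if df <= 0:
        raise ValueError(f"non-positive residual df ({df})")
    xx = (Xr * Xr).sum(axis=0)
    by_gene = pairs.pairs.groupby("gene_id", sort=False)
    out = []
    n_skipped = 0
    gene_col = {g: j for j, g in enumerate(genes)}
    for gene, sub in by_gene:
        if gene not in gene_col:
            continue
        vids = list(sub["variant_id"])
        jx = np.array([xr_index[v] for v in vids])
        keep = ~const_mask[jx]
        if not keep.all():
            n_skipped += int((~keep).sum())
        jx = jx[keep]
        if jx.size == 0:
            continue
        y = Yr[:, gene_col[gene]]
        yy = float(y @ y)
        xy = Xr[:, jx].T @ y
        b = xy / xx[jx]
        rss = np.maximum(yy - b * xy, 0.0)
        se = np.sqrt(rss / df / xx[jx])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, b / se, np.inf * np.sign(b))
        p = floor_p(2.0 * sps.t.sf(np.abs(t), df))
        out.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "variant": np.asarray(vids)[keep],
                    "beta": b,
                    "se": se,
                    "t": t,
                    "p_nominal": p,
                    "n": n,
                }
            )
        )
    if n_skipped:
        logger.warning("skipped %d pairs with constant dosage", n_skipped)
    table = (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(columns=["gene", "variant", "beta", "se", "t", "p_nominal", "n"])
    )
    return EqtlTable(table)


def permute_min_p(
    expr: pd.DataFrame,
    geno: GenotypeMatrix,
    covars: CovariateMatrix | None,
    pairs: CisPairIndex,
    n_perm: int,
    seed: int,
    donor_map: dict[str, str] | None = None,
) -> PermNull:
    """Per-gene permuted minimum nominal p-values.

    Covariates are regressed out of expression once; each permutation round
    shuffles the residualized expression across samples with one shared
    permutation for all genes, refits every cis pair, and records the
    per-gene minimum p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes, var_ids, xr_index, const_mask, Xr, Yr, n, p_model = _prepare(
        expr, geno, covars, pairs, donor_map
    )
    df = n - p_model
    xx = (Xr * Xr).sum(axis=0)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)  # n x n_perm
    by_gene = {g: sub for g, sub in pairs.pairs.groupby("gene_id", sort=False)}
    gene_col = {g: j for j, g in enumerate(genes)}
    minp = np.ones((len(genes), n_perm))
    for gi, gene in enumerate(genes):
        sub = by_gene[gene]
        jx = np.array([xr_index[v] for v in sub["variant_id"]])
        jx = jx[~const_mask[jx]]
        if jx.size == 0:
            continue
        y = Yr[:, gene_col[gene]]
        yy = float(y @ y)
        Yp = y[perms]  # n x n_perm
        C = Xr[:, jx].T @ Yp  # m x n_perm
        with np.errstate(divide="ignore", invalid="ignore"):
            b2xx = C * C / xx[jx][:, None]
            rss = np.maximum(yy - b2xx, 1e-300)
            t2 = b2xx * df / rss
        tmax = np.sqrt(t2.max(axis=0))
        minp[gi] = floor_p(2.0 * sps.t.sf(tmax, df))
    frame = pd.DataFrame(minp, index=genes, columns=[f"perm{j}" for j in range(n_perm)])
    return PermNull(frame, n_perm, seed)


def call_signals(
    table: EqtlTable,
    null: PermNull,
    q_level: float = 0.05,
    elnc_rule: str = "bh",
) -> EqtlCalls:
    """elncRNA calls and per-elncRNA eSNP sets.

    empirical_p = (1 + #{permuted min-p <= observed min-p}) / (n_perm + 1);
    ties count as exceedances. BH across genes gives q; the elncRNA rule is
    q < q_level (``bh``, default) or empirical_p < q_level (``raw``). The
    per-elncRNA eSNP threshold is the empirical 5th percentile of its
    permuted minimum-p vector; eSNPs are its cis variants with nominal
    p <= that threshold.
    """
    if elnc_rule not in ("bh", "raw"):
        raise ValueError("elnc_rule must be 'bh' or 'raw'")
    obs = table.min_p_per_gene()
    genes = list(obs.index)
    missing = [g for g in genes if g not in null.min_p.index]
    if missing:
        raise ValueError(f"genes missing from permutation null: {missing[:5]}")
    emp = np.empty(len(genes))
    thr = np.empty(len(genes))
    for i, g in enumerate(genes):
        v = null.min_p.loc[g].to_numpy(float)
        emp[i] = (1.0 + np.sum(v <= obs[g])) / (null.n_perm + 1.0)
        thr[i] = np.quantile(v, 0.05)
    q = bh_adjust(emp)
    is_e = q < q_level if elnc_rule == "bh" else emp < q_level
    frame = pd.DataFrame(
        {
            "gene": genes,
            "min_p_obs": obs.to_numpy(float),
            "empirical_p": emp,
            "q": q,
            "is_elncRNA": is_e,
            "esnp_threshold": thr,
        }
    )
    esnps: dict[str, set[str]] = {}
    tab = table.table
    for g, t in zip(frame.loc[frame["is_elncRNA"], "gene"], frame.loc[frame["is_elncRNA"], "esnp_threshold"]):
        sub = tab[(tab["gene"] == g) & (tab["p_nominal"] <= t)]
        esnps[g] = set(sub["variant"])
    return EqtlCalls(frame, esnps)


def select_non_esnps(
    table: EqtlTable,
    geno: GenotypeMatrix,
    p_floor: float = 0.5,
    r2: float = 0.8,
) -> set[str]:
    """Background variant set: cis variants with nominal p > p_floor for
    every gene testing them, LD-pruned at r-squared > ``r2`` (greedy by
    position)."""
    from .enrichment import ld_filter

    worst = table.table.groupby("variant")["p_nominal"].min()
    candidates = set(worst.index[worst > p_floor])
    if not candidates:
        logger.warning("no variants pass the non-eSNP p > %.2f filter", p_floor)
        return set()
    return ld_filter(geno, candidates, r2=r2, mode="prune")
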