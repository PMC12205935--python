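"""Instrumental-variable estimation of lncRNA -> mRNA effects and pathway
readout.

A lncRNA's eSNPs (LD-pruned) instrument its expression: stage 1 regresses
lncRNA expression on the instruments plus covariates, stage 2 regresses
mRNA expression on the fitted lncRNA values. Because genotypes are
randomized at meiosis, the two-stage estimate is robust to hidden
confounders that bias naive co-expression regression. Downstream lncRNAs
get pathway readout via preranked GSEA and hypergeometric overlap tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, floor_p
from .types import (
    CausalEstimate,
    CovariateMatrix,
    EqtlCalls,
    ExpressionPanel,
    GeneModel,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)

WEAK_F = 10.0


def fit_2sls(
    mrna_expr: np.ndarray,
    lnc_expr: np.ndarray,
    instruments: np.ndarray,
    covars: np.ndarray | None = None,
    lnc: str = "",
    mrna: str = "",
    instrument_ids: list[str] | None = None,
) -> CausalEstimate:
    """Two-stage least squares for one (lncRNA, mRNA) pair.

    Stage 1: lnc ~ instruments + covars; stage 2: mrna ~ fitted(lnc) +
    covars. The SE uses the standard 2SLS residual: stage-2 coefficients
    with the *observed* lncRNA expression, df = n - p. The first-stage
    partial F of the instruments is reported; F < 10 flags a weak
    instrument but does not suppress the estimate.
    """
    y = np.asarray(mrna_expr, float)
    x = np.asarray(lnc_expr, float)
    Z = np.atleast_2d(np.asarray(instruments, float))
    if Z.shape[0] != len(y):
        Z = Z.T
    n = len(y)
    if Z.shape[1] < 1:
        raise ValueError("at least one instrument required")
    C = np.ones((n, 1)) if covars is None else np.column_stack([np.ones(n), covars])
    W1 = np.column_stack([C, Z])  # stage-1 design
    if np.linalg.matrix_rank(W1) < W1.shape[1]:
        raise ValueError("instruments collinear with covariates")
    p2 = C.shape[1] + 1  # stage-2 params: covars + intercept + lnc
    if n <= max(W1.shape[1], p2):
        raise ValueError(f"n={n} too small for the model")

    # stage 1 + partial F of the instruments
    beta1, *_ = np.linalg.lstsq(W1, x, rcond=None)
    xhat = W1 @ beta1
    rss_full = float(np.sum((x - xhat) ** 2))
    bC, *_ = np.linalg.lstsq(C, x, rcond=None)
    rss_red = float(np.sum((x - C @ bC) ** 2))
    df1 = n - W1.shape[1]
    k = Z.shape[1]
    F = max(0.0, (rss_red - rss_full) / k / (rss_full / df1)) if rss_full > 0 else np.inf

    # stage 2 on fitted values
    W2 = np.column_stack([C, xhat])
    XtX = W2.T @ W2
    coef = np.linalg.solve(XtX, W2.T @ y)
    beta_iv = float(coef[-1])
    # 2SLS residual uses observed lnc expression with the 2SLS coefficients
    resid = y - np.column_stack([C, x]) @ coef
    df = n - p2
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * np.linalg.inv(XtX)[-1, -1]))
    t = beta_iv / se if se > 0 else np.inf * np.sign(beta_iv)
    p = float(floor_p(2.0 * sps.t.sf(abs(t), df)))
    return CausalEstimate(
        lnc=lnc,
        mrna=mrna,
        beta_iv=beta_iv,
        se=se,
        p=p,
        first_stage_F=float(F),
        instruments=list(instrument_ids or []),
    )


def causal_scan(
    twas_hits: list[str],
    panel: ExpressionPanel,
    calls: EqtlCalls,
    geno: GenotypeMatrix,
    covars_per_tissue: dict[str, CovariateMatrix | None],
    genes: list[GeneModel],
    mrna_ids: list[str] | None = None,
    q_level: float = 0.05,
    r2: float = 0.8,
) -> list[CausalEstimate]:
    """2SLS scan of every (TWAS-hit lncRNA, mRNA) pair per tissue.

    Instruments are the lncRNA's eSNPs LD-pruned at r^2 > ``r2``. BH runs
    across the whole scan; same-chromosome pairs carry a signed TSS
    distance. lncRNAs without eSNPs are skipped and logged.
    """
    from .enrichment import ld_filter

    gmap = {g.gene_id: g for g in genes}
    if mrna_ids is None:
        mrna_ids = [g.gene_id for g in genes if g.is_coding and g.gene_id in panel.gene_ids]
    gidx = {s: i for i, s in enumerate(geno.samples)}
    results: list[CausalEstimate] = []
    for tid, tis in panel.tissues.items():
        rows = [gidx[tis.donor_map[s]] for s in tis.samples]
        cov = covars_per_tissue.get(tid)
        Cv = cov.values() if cov is not None else None
        for lnc in twas_hits:
            esnps = calls.esnps.get(lnc, set())
            if not esnps:
                logger.warning("lncRNA %s has no eSNPs; skipped in causal scan", lnc)
                continue
            inst_ids = sorted(ld_filter(geno, esnps, r2=r2, mode="prune"))
            Z = geno.dosages[np.ix_(rows, [geno.column_index(v) for v in inst_ids])].astype(float)
            x = tis.matrix.loc[lnc].to_numpy(float)
            for mrna in mrna_ids:
                if mrna == lnc:
                    continue
                y = tis.matrix.loc[mrna].to_numpy(float)
                try:
                    est = fit_2sls(y, x, Z, Cv, lnc=lnc, mrna=mrna, instrument_ids=inst_ids)
                except (ValueError, np.linalg.LinAlgError) as err:
                    logger.warning("2SLS %s->%s (%s) failed: %s", lnc, mrna, tid, err)
                    continue
                est.tissue = tid
                gl, gm = gmap[lnc], gmap[mrna]
                if gl.chrom == gm.chrom:
                    est.tss_distance = gm.tss - gl.tss
                results.append(est)
    if results:
        qs = bh_adjust([e.p for e in results])
        for e, q in zip(results, qs):
            e.q = float(q)
    return results


def coexpression(
    lnc_ids: list[str], panel_tissue, mrna_ids: list[str]
) -> pd.DataFrame:
    """Pairwise Pearson correlation of lncRNA and mRNA expression within one
    tissue, with two-sided t-approximation p-values. Constant vectors are
    flagged undefined."""
    mat = panel_tissue.matrix
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    rows = []
    for l in lnc_ids:
        x = mat.loc[l].to_numpy(float)
        for m in mrna_ids:
            y = mat.loc[m].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"lnc": l, "mrna": m, "pearson_r": np.nan, "p": np.nan, "undefined": True})
                continue
            r, p = sps.pearsonr(x, y)
            rows.append({"lnc": l, "mrna": m, "pearson_r": float(r), "p": float(p), "undefined": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pathway readout


def _es_running_sum(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = len(in_set)
    n_miss = n - int(in_set.sum())
    w_hit = np.where(in_set, weights, 0.0)
    denom_hit = w_hit.sum()
    if denom_hit == 0:
        # all-zero scores inside the set: fall back to unweighted hits
        w_hit = in_set.astype(float)
        denom_hit = w_hit.sum()
    p_hit = np.cumsum(w_hit) / denom_hit
    p_miss = np.cumsum(~in_set) / max(1, n_miss)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def preranked_gsea(
    scores: pd.Series,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutations.

    Genes are ranked by score descending (ties broken by gene id); the
    enrichment score is the signed maximum of the weighted KS running sum
    with weight |score|^exponent. The permutation p counts permuted ES at
    least as extreme in magnitude, with the +1 convention so p >=
    1/(n_perm+1); NES divides ES by the mean |permuted ES| of the same
    sign. Sets smaller than ``min_size`` after intersection are skipped.
    """
    rng = np.random.default_rng(seed)
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    s = scores.loc[order].to_numpy(float)
    w = np.abs(s) ** weight_exponent
    gene_pos = {g: i for i, g in enumerate(order)}
    n = len(order)
    rows = []
    for name, members in gene_sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(idx) < min_size:
            logger.info("gene set %s skipped (size %d < %d)", name, len(idx), min_size)
            continue
        mask = np.zeros(n, bool)
        mask[idx] = True
        es = _es_running_sum(mask, w)
        k = len(idx)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            pm = np.zeros(n, bool)
            pm[rng.choice(n, size=k, replace=False)] = True
            perm_es[b] = _es_running_sum(pm, w)
        exceed = np.abs(perm_es) >= abs(es)
        p = (1.0 + int(exceed.sum())) / (n_perm + 1.0)
        same = perm_es >= 0 if es >= 0 else perm_es <= 0
        denom = np.mean(np.abs(perm_es[same])) if same.any() else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        rows.append(
            {"gene_set": name, "method": "gsea", "ES": es, "NES": nes, "size": k, "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out


def pathway_hypergeom(
    affected: set[str], gene_sets: dict[str, set[str]], background: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of an affected-gene set in each
    pathway; BH across pathways."""
    if not affected <= background:
        raise ValueError("affected genes must be contained in the background")
    N = len(background)
    rows = []
    for name, members in gene_sets.items():
        m = members & background
        if len(members) > N:
            raise ValueError(f"gene set {name!r} larger than the background")
        k = len(affected & m)
        p = float(sps.hypergeom.sf(k - 1, N, len(m), len(affected)))
        rows.append({"gene_set": name, "method": "hypergeom", "overlap": k, "size": len(m), "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out


def select_for_pathways(twas_table: pd.DataFrame, causal: list[CausalEstimate],
                        q_twas: float = 0.1, min_targets: int = 20) -> list[str]:
    """lncRNAs eligible for pathway readout: TWAS q < ``q_twas`` and more
    than ``min_targets`` significantly affected mRNAs in the causal scan."""
    sig_targets: dict[str, set[str]] = {}
    for e in causal:
        if e.q is not None and e.q < 0.05:
            sig_targets.setdefault(e.lnc, set()).add(e.mrna)
    hits = twas_table[twas_table["q"] < q_twas]["gene"] if len(twas_table) else []
    return [g for g in hits if len(sig_targets.get(g, set())) > min_targets]
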