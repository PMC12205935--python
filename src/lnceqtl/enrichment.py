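"""Uniform 2x2 enrichment machinery and its applications.

One exact-test core (`fisher_enrichment`) serves four scans: variant
functional classes, TF binding peaks, MAF bins, and disease risk loci.
Also provides LD pruning/expansion on dosage columns and the signed
TSS-distance profile of eSNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .types import (
    EnrichmentResult,
    EqtlCalls,
    GeneModel,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = (
    "splicing",
    "exonic",
    "UTR5",
    "UTR3",
    "ncRNA_splicing",
    "ncRNA_exonic",
    "intronic",
    "ncRNA_intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_SPLICE_BP = 2
_FLANK_BP = 1000


# ---------------------------------------------------------------------------
# Fisher core


def fisher_enrichment(
    a: int, b: int, c: int, d: int, zero_correction: float = 0.5, label: str = ""
) -> EnrichmentResult:
    """Two-tailed Fisher's exact test with cross-product OR and Woolf CI.

    p sums hypergeometric tables (fixed margins) whose point probability is
    at or below the observed table's. The OR is ad/bc, with the Haldane
    half-count correction applied to every cell only when some cell is
    zero; the 95% CI is exp(log OR +- 1.96 * sqrt(sum of reciprocal
    corrected counts)).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("a Fisher margin (row total) is zero")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    h = zero_correction if 0 in (a, b, c, d) else 0.0
    aa, bb, cc, dd = a + h, b + h, c + h, d + h
    or_est = (aa * dd) / (bb * cc)
    se_log = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = float(np.exp(np.log(or_est) - 1.96 * se_log))
    ci_high = float(np.exp(np.log(or_est) + 1.96 * se_log))
    return EnrichmentResult(label, a, b, c, d, float(or_est), ci_low, ci_high, float(p))


# ---------------------------------------------------------------------------
# LD utilities


def _dosage_submatrix(geno: GenotypeMatrix, variant_ids: list[str]) -> np.ndarray:
    cols = [geno.column_index(v) for v in variant_ids]
    X = geno.dosages[:, cols].astype(float)
    # mean-impute missing entries (encoded as NaN when read from files)
    if np.isnan(X).any():
        mu = np.nanmean(X, axis=0)
        ii = np.where(np.isnan(X))
        X[ii] = mu[ii[1]]
    return X - X.mean(axis=0)


def _r2_matrix(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd = np.where(sd == 0, np.nan, sd)
    C = (X.T @ X) / X.shape[0]
    R = C / np.outer(sd, sd)
    return R**2


def ld_filter(
    geno: GenotypeMatrix,
    variants: set[str] | list[str],
    r2: float = 0.8,
    mode: str = "prune",
    index_set: set[str] | None = None,
    window: int = 500,
) -> set[str]:
    """LD pruning or expansion at squared-correlation threshold ``r2``.

    prune: scan variants in genomic order, retaining each unless its r^2
    with a retained predecessor within the trailing ``window`` retained
    variants exceeds the threshold. expand: return all candidate variants
    with r^2 > threshold to any index variant, plus the index set itself.
    r^2 is computed on mean-imputed, centered dosages.
    """
    variants = set(variants)
    for v in variants | (index_set or set()):
        geno.column_index(v)  # raises naming the missing variant
    vtab = geno.variants
    ordered = [v for v in vtab["variant_id"] if v in variants]
    if mode == "prune":
        X = _dosage_submatrix(geno, ordered)
        sd = X.std(axis=0)
        kept_idx: list[int] = []
        n = X.shape[0]
        for j in range(len(ordered)):
            recent = kept_idx[-window:]
            ok = True
            if recent and sd[j] > 0:
                r = (X[:, recent].T @ X[:, j]) / n / (sd[recent] * sd[j])
                ok = not np.any(r**2 > r2)
            elif recent and sd[j] == 0:
                ok = True  # constant column: undefined r^2, keep
            if ok:
                kept_idx.append(j)
        return {ordered[j] for j in kept_idx}
    if mode == "expand":
        if index_set is None:
            raise ValueError("expand mode requires an index set")
        index = [v for v in vtab["variant_id"] if v in set(index_set)]
        if not index:
            return set()
        Xc = _dosage_submatrix(geno, ordered) if ordered else np.empty((geno.n_individuals, 0))
        Xi = _dosage_submatrix(geno, index)
        out = set(index_set)
        if ordered:
            n = Xc.shape[0]
            sdc = Xc.std(axis=0)
            sdi = Xi.std(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                R = (Xc.T @ Xi) / n / np.outer(sdc, sdi)
            hit = np.nanmax(R**2, axis=1) > r2
            out |= {v for v, keep in zip(ordered, hit) if keep}
        return out
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# functional classification


@dataclass
class _GeneIntervals:
    gene: GeneModel
    splice_sites: list[tuple[int, int]]
    introns: list[tuple[int, int]]


def _intervals(gene: GeneModel) -> _GeneIntervals:
    introns = []
    splice = []
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if s2 > e1 + 1:
            introns.append((e1 + 1, s2 - 1))
            splice.append((e1 + 1, min(e1 + _SPLICE_BP, s2 - 1)))
            splice.append((max(s2 - _SPLICE_BP, e1 + 1), s2 - 1))
    return _GeneIntervals(gene, splice, introns)


def _in(pos: int, ivals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in ivals)


def _classes_for_gene(pos: int, gi: _GeneIntervals) -> set[str]:
    g = gi.gene
    out: set[str] = set()
    if g.start <= pos <= g.end:
        in_exon = _in(pos, g.exons)
        if g.is_coding:
            if _in(pos, gi.splice_sites):
                out.add("splicing")
            if in_exon:
                cs, ce = g.cds if g.cds else (g.start, g.end)
                if cs <= pos <= ce:
                    out.add("exonic")
                else:
                    five_prime = pos < cs if g.strand == "+" else pos > ce
                    out.add("UTR5" if five_prime else "UTR3")
            elif _in(pos, gi.introns):
                out.add("intronic")
        else:
            if _in(pos, gi.splice_sites):
                out.add("ncRNA_splicing")
            if in_exon:
                out.add("ncRNA_exonic")
            elif _in(pos, gi.introns):
                out.add("ncRNA_intronic")
    # 1 kb flanks, strand-aware
    if g.strand == "+":
        if g.start - _FLANK_BP <= pos < g.start:
            out.add("upstream")
        if g.end < pos <= g.end + _FLANK_BP:
            out.add("downstream")
    else:
        if g.end < pos <= g.end + _FLANK_BP:
            out.add("upstream")
        if g.start - _FLANK_BP <= pos < g.start:
            out.add("downstream")
    return out


def classify_variant(
    variants: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Assign each variant exactly one of the 11 functional classes.

    ``variants`` needs columns (variant_id, chrom, pos). Classes gathered
    over all overlapping genes are resolved by the fixed precedence order
    in ``FUNCTIONAL_CLASSES``; a variant touching no gene or flank (or on a
    chromosome absent from the models) is intergenic.
    """
    by_chrom: dict[str, list[_GeneIntervals]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(_intervals(g))
    rank = {c: i for i, c in enumerate(FUNCTIONAL_CLASSES)}
    labels = []
    for _, row in variants.iterrows():
        cands: set[str] = set()
        for gi in by_chrom.get(row["chrom"], []):
            cands |= _classes_for_gene(int(row["pos"]), gi)
        labels.append(min(cands, key=rank.get) if cands else "intergenic")
    return pd.DataFrame(
        {"variant_id": variants["variant_id"].to_numpy(), "functional_class": labels}
    )


def functional_enrichment(
    esnps: set[str],
    non_esnps: set[str],
    annotation: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Per-class Fisher enrichment of eSNPs versus non-eSNPs (BH over classes)."""
    ann = annotation.set_index("variant_id")["functional_class"]
    fg = ann.loc[ann.index.intersection(list(esnps))]
    bg = ann.loc[ann.index.intersection(list(non_esnps))]
    results = []
    for cls in FUNCTIONAL_CLASSES:
        a = int((fg == cls).sum())
        b = len(fg) - a
        c = int((bg == cls).sum())
        d = len(bg) - c
        if a + c == 0:
            continue
        results.append(fisher_enrichment(a, b, c, d, label=cls))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# TF peaks


def variants_in_peaks(
    geno: GenotypeMatrix, peaks: pd.DataFrame
) -> set[str]:
    """Variant ids whose position falls inside any peak interval (1-based
    inclusive, plain membership)."""
    out: set[str] = set()
    v = geno.variants
    for chrom, sub in peaks.groupby("chrom"):
        vv = v[v["chrom"] == chrom]
        if vv.empty:
            continue
        # merge overlapping peaks so a sorted lookup is exact
        merged: list[list[int]] = []
        for s, e in sub.sort_values("start")[["start", "end"]].itertuples(index=False):
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        pos = vv["pos"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        hit = (j >= 0) & (pos <= ends[np.clip(j, 0, None)])
        out |= set(vv.loc[hit, "variant_id"])
    return out


def tf_peak_enrichment(
    esnps: set[str],
    non_esnps: set[str],
    tf_peaks: dict[str, pd.DataFrame],
    geno: GenotypeMatrix,
) -> list[EnrichmentResult]:
    """Per-TF Fisher enrichment of eSNP peak membership vs non-eSNPs."""
    results = []
    for tf, peaks in tf_peaks.items():
        inside = variants_in_peaks(geno, peaks)
        a = len(esnps & inside)
        b = len(esnps) - a
        c = len(non_esnps & inside)
        d = len(non_esnps) - c
        results.append(fisher_enrichment(a, b, c, d, label=tf))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# MAF bins


@dataclass
class MafBinResult:
    bins: pd.DataFrame  # bin_low, bin_high, esnp_prop, non_esnp_prop, OR, p, q
    trend_slope: float
    trend_r: float
    trend_p: float
    per_bin: list[EnrichmentResult]


def maf_bin_analysis(
    esnps: set[str] | dict[str, set[str]],
    non_esnps: set[str],
    geno: GenotypeMatrix,
) -> MafBinResult:
    """eSNP vs non-eSNP composition across 5%-wide MAF bins on [0.05, 0.50].

    Per bin: the proportion of each set falling in the bin and a Fisher test
    of bin membership (eSNPs vs non-eSNPs). The trend is an OLS fit of the
    per-bin median eSNP proportion on the bin midpoint — the median is over
    tissues when ``esnps`` is a per-tissue dict, and degenerates to the
    single proportion otherwise. Empty bins are excluded from the trend.
    """
    maf = geno.variants.set_index("variant_id")["maf_observed"]
    tissue_sets = esnps if isinstance(esnps, dict) else {"all": esnps}
    union_esnps = set().union(*tissue_sets.values())
    if not union_esnps or not non_esnps:
        raise ValueError("both eSNP and non-eSNP sets must be nonempty")
    for s in (union_esnps, non_esnps):
        vals = maf.loc[list(s)]
        if (vals < 0.05).any():
            raise ValueError("variants below the MAF >= 0.05 QC floor present")
    edges = np.round(np.arange(0.05, 0.501, 0.05), 10)
    mids = (edges[:-1] + edges[1:]) / 2

    def bin_counts(vs: set[str]) -> np.ndarray:
        m = maf.loc[list(vs)].to_numpy()
        # half-open bins; np.histogram closes the final edge, folding 0.50 in
        counts, _ = np.histogram(m, bins=edges)
        return counts

    ce = bin_counts(union_esnps)
    cn = bin_counts(non_esnps)
    e_union = ce / max(1, ce.sum())
    ne = cn / max(1, cn.sum())
    per_tissue = np.vstack(
        [bin_counts(s) / max(1, len(s)) for s in tissue_sets.values()]
    )
    med = np.median(per_tissue, axis=0)

    n_e, n_ne = len(union_esnps), len(non_esnps)
    per_bin = []
    rows = []
    for i in range(len(mids)):
        a, c = int(ce[i]), int(cn[i])
        res = fisher_enrichment(a, n_e - a, c, n_ne - c, label=f"maf_{edges[i]:.2f}")
        per_bin.append(res)
        rows.append(
            {
                "bin_low": edges[i],
                "bin_high": edges[i + 1],
                "esnp_prop": e_union[i],
                "non_esnp_prop": ne[i],
                "median_esnp_prop": med[i],
                "OR": res.or_estimate,
                "p": res.p,
            }
        )
    qs = bh_adjust([r.p for r in per_bin])
    for r, q in zip(per_bin, qs):
        r.q = float(q)
    frame = pd.DataFrame(rows)
    frame["q"] = qs
    nonempty = (e_union > 0) | (ne > 0)
    x, y = mids[nonempty], med[nonempty]
    if len(x) >= 3 and np.ptp(y) > 0:
        lr = sps.linregress(x, y)
        slope, r_val, p_val = float(lr.slope), float(lr.rvalue), float(lr.pvalue)
    else:
        slope, r_val, p_val = float("nan"), float("nan"), float("nan")
    return MafBinResult(frame, slope, r_val, p_val, per_bin)


# ---------------------------------------------------------------------------
# disease scan


def disease_scan(
    esnps: set[str] | dict[str, set[str]],
    non_esnps: set[str],
    disease_sets: dict[str, set[str]],
    geno: GenotypeMatrix,
    r2: float = 0.8,
    q_level: float = 0.05,
) -> list[EnrichmentResult]:
    """Risk-loci enrichment: each disease's index variants are LD-expanded
    at r^2 > ``r2``, then eSNP vs non-eSNP membership among disease SNPs is
    Fisher-tested, per disease (x tissue for a per-tissue dict), with BH
    over all tests. Diseases whose expanded set misses the background are
    skipped with a log entry."""
    tissue_sets = esnps if isinstance(esnps, dict) else {"all": esnps}
    background = set().union(*tissue_sets.values()) | set(non_esnps)
    results = []
    for disease, index_set in disease_sets.items():
        missing = index_set - set(geno.variants["variant_id"])
        if missing:
            logger.warning("disease %s: %d index variants absent, dropped", disease, len(missing))
        idx = index_set - missing
        if not idx:
            logger.warning("disease %s skipped: no resolvable index variants", disease)
            continue
        expanded = ld_filter(geno, background, r2=r2, mode="expand", index_set=idx)
        dset = expanded & background
        if not dset:
            logger.warning("disease %s skipped: expansion disjoint from background", disease)
            continue
        for tissue, eset in tissue_sets.items():
            if not eset:
                logger.warning("disease %s, tissue %s: empty eSNP set, skipped", disease, tissue)
                continue
            a = len(eset & dset)
            b = len(eset - dset)
            c = len(non_esnps & dset)
            d = len(non_esnps - dset)
            label = disease if tissue == "all" else f"{disease}|{tissue}"
            results.append(fisher_enrichment(a, b, c, d, label=label))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# TSS distance profile


def tss_distance_profile(
    calls: EqtlCalls,
    genes: list[GeneModel],
    binsize: int = 10_000,
    geno: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Percentage of eSNPs per signed TSS-distance bin.

    Distance is strand-aware: negative means upstream of the TSS in the
    gene's reading direction. Bin edges are multiples of ``binsize``; the
    returned percentages sum to 100.
    """
    if geno is None:
        raise ValueError("a genotype matrix is required for variant positions")
    pos = geno.variants.set_index("variant_id")["pos"]
    gmap = {g.gene_id: g for g in genes}
    dists = []
    for gene_id, vset in calls.esnps.items():
        g = gmap[gene_id]
        sign = 1 if g.strand == "+" else -1
        for v in vset:
            dists.append(sign * (int(pos[v]) - g.tss))
    if not dists:
        raise ValueError("no eSNPs to profile")
    d = np.asarray(dists)
    bins = np.floor(d / binsize).astype(int)
    counts = pd.Series(bins).value_counts().sort_index()
    out = pd.DataFrame(
        {
            "bin_low": counts.index * binsize,
            "bin_high": (counts.index + 1) * binsize,
            "percentage": 100.0 * counts.to_numpy() / len(d),
        }
    )
    return out.reset_index(drop=True)
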