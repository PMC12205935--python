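"""Cross-region characterization of elncRNAs.

Region-vs-rest differential expression, Jaccard similarity of elncRNA sets,
hypergeometric overlap tests, Wilcoxon feature comparisons, and the
error-corrected cross-tissue effect-size correlation (rb): the correlation
of *true* genetic effects between two tissues estimated from noisy per-pair
(beta, se) estimates by subtracting estimation-error variance and the
shared-sample error covariance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .types import EqtlTable, ExpressionPanel, RbEstimate

logger = logging.getLogger(__name__)


def differential_expression(
    panel: ExpressionPanel,
    region: str,
    fc_threshold: float = 1.5,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test of one region versus all other regions pooled.

    Expression is on the log2 scale, so log2FC is the difference of group
    means and FC = 2**log2FC. A gene is differentially expressed iff
    |FC| direction-symmetrically exceeds ``fc_threshold`` (i.e. |log2FC| >
    log2(fc_threshold)) and BH q < ``q_level``.
    """
    if region not in panel.tissues:
        raise ValueError(f"region {region!r} not in panel")
    A = panel.tissues[region].matrix.to_numpy(float)
    rest = [t.matrix.to_numpy(float) for tid, t in panel.tissues.items() if tid != region]
    if not rest:
        raise ValueError("need at least two regions")
    B = np.concatenate(rest, axis=1)
    if A.shape[1] < 3 or B.shape[1] < 3:
        raise ValueError("fewer than 3 samples on one side")
    t, p = sps.ttest_ind(A, B, axis=1, equal_var=False)
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    q = bh_adjust(p)
    is_de = (np.abs(log2fc) > np.log2(fc_threshold)) & (q < q_level)
    return pd.DataFrame(
        {
            "gene": panel.gene_ids,
            "region": region,
            "log2FC": log2fc,
            "FC": 2.0**log2fc,
            "t": t,
            "p": p,
            "q": q,
            "is_de": is_de,
        }
    )


def jaccard_matrix(sets: dict[str, set[str]]) -> pd.DataFrame:
    """J(A,B) = |A n B| / |A u B| for every region pair; J of two empty
    sets is 0 (logged)."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    names = list(sets)
    M = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            A, B = sets[a], sets[names[j]]
            union = A | B
            if not union:
                logger.warning("Jaccard of two empty sets (%s, %s) defined as 0", a, names[j])
                val = 0.0
            else:
                val = len(A & B) / len(union)
            M[i, j] = M[j, i] = val
    return pd.DataFrame(M, index=names, columns=names)


def hypergeom_overlap(
    set_a: set[str], set_b: set[str], background: set[str]
) -> tuple[int, float, float]:
    """Upper-tail overlap test: P[X >= observed] for X hypergeometric with
    population ``background``. Returns (overlap, expected, p)."""
    if not set_a <= background or not set_b <= background:
        raise ValueError("sets must be contained in the background")
    N, K, n = len(background), len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = K * n / N if N else 0.0
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return k, expected, p


def feature_compare(
    features: pd.DataFrame,
    group_a: set[str],
    group_b: set[str],
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of each numeric feature
    between two gene groups.

    Exact enumeration when both groups have <= 10 observations, otherwise
    the tie-corrected normal approximation. Features where every value is
    tied across both groups get p = 1 (logged).
    """
    rows = []
    for feat in features.columns:
        x = features.loc[features.index.intersection(list(group_a)), feat].dropna()
        y = features.loc[features.index.intersection(list(group_b)), feat].dropna()
        if len(x) < 3 or len(y) < 3:
            raise ValueError(f"feature {feat!r}: fewer than 3 observations in a group")
        if np.ptp(np.concatenate([x, y])) == 0:
            logger.warning("feature %s: all values tied; p = 1", feat)
            rows.append({"feature": feat, "W": len(x) * len(y) / 2.0, "p": 1.0})
            continue
        method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"feature": feat, "W": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rb: error-corrected cross-tissue effect correlation


def _top_pairs(table_a: EqtlTable, table_b: EqtlTable) -> pd.DataFrame:
    """Per shared gene, the tissue-A top association (minimum p) matched to
    the same (gene, variant) row in tissue B."""
    ta, tb = table_a.table, table_b.table
    top = ta.loc[ta.groupby("gene")["p_nominal"].idxmin(), ["gene", "variant", "beta", "se"]]
    top = top.rename(columns={"beta": "b1", "se": "se1"})
    merged = top.merge(
        tb[["gene", "variant", "beta", "se"]].rename(columns={"beta": "b2", "se": "se2"}),
        on=["gene", "variant"],
        how="inner",
    )
    return merged


def estimate_error_correlation(
    table_a: EqtlTable, table_b: EqtlTable, null_variants: set[str]
) -> float:
    """Correlation of estimation errors between tissues with shared donors,
    estimated as the Pearson correlation of z-scores over null (gene,
    variant) pairs — pairs whose variants carry no signal in either tissue."""
    ta = table_a.table
    tb = table_b.table
    a = ta[ta["variant"].isin(null_variants)][["gene", "variant", "t"]]
    b = tb[tb["variant"].isin(null_variants)][["gene", "variant", "t"]]
    m = a.merge(b, on=["gene", "variant"], suffixes=("_1", "_2"))
    if len(m) < 10:
        raise ValueError("fewer than 10 shared null pairs for error correlation")
    return float(np.corrcoef(m["t_1"], m["t_2"])[0, 1])


def _rb_point(b1, se1, b2, se2, r_e) -> float:
    var1 = np.var(b1) - np.mean(se1**2)
    var2 = np.var(b2) - np.mean(se2**2)
    if var1 <= 0 or var2 <= 0:
        raise ValueError("effect variance below error variance; rb undefined")
    cov = float(np.cov(b1, b2, ddof=0)[0, 1]) - r_e * float(np.mean(se1 * se2))
    return cov / np.sqrt(var1 * var2)


def estimate_rb(
    table_a: EqtlTable,
    table_b: EqtlTable,
    null_variants: set[str],
) -> RbEstimate:
    """Error-corrected correlation of true cis effects between two tissues.

    Using per-gene top-association pairs (b1, se1), (b2, se2):
        var_true_i = var(b_i) - mean(se_i^2)
        cov_true   = cov(b1, b2) - r_e * mean(se1 * se2)
        rb         = cov_true / sqrt(var_true_1 * var_true_2)
    where r_e, the error correlation induced by shared donors, is the
    z-score correlation over null variants. The SE is a leave-one-gene-out
    jackknife; rb is clamped to [-1, 1] with a flag.
    """
    pairs = _top_pairs(table_a, table_b)
    if len(pairs) < 10:
        raise ValueError(f"only {len(pairs)} shared top pairs; >= 10 required")
    r_e = estimate_error_correlation(table_a, table_b, null_variants)
    b1 = pairs["b1"].to_numpy(float)
    se1 = pairs["se1"].to_numpy(float)
    b2 = pairs["b2"].to_numpy(float)
    se2 = pairs["se2"].to_numpy(float)
    rb = _rb_point(b1, se1, b2, se2, r_e)
    n = len(pairs)
    jack = []
    for i in range(n):
        m = np.ones(n, bool)
        m[i] = False
        try:
            jack.append(_rb_point(b1[m], se1[m], b2[m], se2[m], r_e))
        except ValueError:
            continue
    jack = np.asarray(jack)
    se = float(np.sqrt((len(jack) - 1) / len(jack) * np.sum((jack - jack.mean()) ** 2)))
    clamped = not (-1.0 <= rb <= 1.0)
    rb = float(np.clip(rb, -1.0, 1.0))
    return RbEstimate(rb=rb, se=se, n_pairs=n, r_e=r_e, clamped=clamped)
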