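"""Covariate construction and expression preprocessing.

Builds the covariate set used by every downstream fit: genotype principal
components capture ancestry structure, and hidden expression factors —
principal components of covariate-residualized expression, standing in for
probabilistic factor models such as PEER — absorb unmodelled technical and
biological variation. Also provides per-gene residualization and the
cross-tissue Z-score outlier screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import CovariateMatrix, ExpressionPanel, FactorSet, GenotypeMatrix, OutlierSet

logger = logging.getLogger(__name__)


def compute_genotype_pcs(geno: GenotypeMatrix, k: int) -> CovariateMatrix:
    """Top-k PC scores of the column-standardized dosage matrix.

    Zero-variance variants are dropped before standardization. Sign
    convention: each component is flipped so its largest-magnitude variant
    loading is positive.
    """
    X = geno.dosages.astype(float)
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] == 0:
        raise ValueError("no variants with nonzero variance")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    max_rank = min(geno.n_individuals - 1, X.shape[1])
    if k > max_rank:
        raise ValueError(f"k={k} exceeds achievable rank {max_rank}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(k)]
    return CovariateMatrix(pd.DataFrame(scores, index=geno.samples, columns=cols))


def _design(covars: CovariateMatrix | None, n: int) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; raises on rank deficiency naming columns."""
    if covars is None or covars.data.shape[1] == 0:
        return np.ones((n, 1)), ["intercept"]
    X = np.column_stack([np.ones(n), covars.values()])
    names = ["intercept"] + covars.names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    return X, names


def residualize(expr: pd.DataFrame, covars: CovariateMatrix | None) -> pd.DataFrame:
    """Per-gene OLS residuals of a genes x samples matrix on the covariates
    (intercept always included). Residuals are exactly orthogonal to every
    covariate column."""
    Y = expr.to_numpy(float).T  # samples x genes
    X, _ = _design(covars, Y.shape[0])
    Q, _ = np.linalg.qr(X)
    R = Y - Q @ (Q.T @ Y)
    return pd.DataFrame(R.T, index=expr.index, columns=expr.columns)


def infer_hidden_factors(
    expr: pd.DataFrame, known: CovariateMatrix | None, k: int
) -> FactorSet:
    """Hidden expression factors: top-k PCs of the expression matrix after
    residualizing every gene on the known covariates.

    This is a deterministic surrogate for probabilistic factor inference
    (PEER-like tools); it recovers broad batch/technical axes but does not
    model factor uncertainty. Variance explained is reported per factor as
    a fraction of total residual variance.
    """
    n_samples = expr.shape[1]
    rank_known = 1 + (0 if known is None else known.data.shape[1])
    if k == 0:
        return FactorSet(pd.DataFrame(index=list(expr.columns)), np.array([]))
    if k >= n_samples - rank_known:
        raise ValueError(
            f"k={k} too large for {n_samples} samples with {rank_known} known covariates"
        )
    R = residualize(expr, known).to_numpy(float).T  # samples x genes
    R = R - R.mean(axis=0)
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    scores = U[:, :k] * s[:k]
    ve = (s[:k] ** 2) / np.sum(s**2)
    cols = [f"HF{j + 1}" for j in range(k)]
    return FactorSet(pd.DataFrame(scores, index=list(expr.columns), columns=cols), ve)


def default_n_hidden_factors(n_samples: int) -> int:
    """min(15, n_samples // 10): 15 factors for cohorts of >= 150 samples,
    proportionally fewer at desk scale to avoid overfitting."""
    return min(15, n_samples // 10)


def zscore_outliers(
    panel: ExpressionPanel,
    covars_per_tissue: dict[str, CovariateMatrix | None],
    threshold: float = 2.0,
) -> OutlierSet:
    """Cross-tissue expression outlier screen.

    Per tissue, expression is residualized on that tissue's covariates and
    Z-scored per gene (population SD, ddof 0); per (gene, donor) the median
    Z across tissues containing the donor is taken; a gene is flagged iff
    some donor's |median Z| is strictly greater than ``threshold``.
    Genes with zero residual variance in any tissue are excluded with a
    logged warning.
    """
    if len(panel.tissues) < 2:
        raise ValueError("outlier screen requires >= 2 tissues")
    z_by_tissue = {}
    excluded: set[str] = set()
    for tid, tis in panel.tissues.items():
        R = residualize(tis.matrix, covars_per_tissue.get(tid))
        vals = R.to_numpy(float)
        sd = vals.std(axis=1, ddof=0)
        zero = sd == 0
        if zero.any():
            bad = list(np.asarray(R.index)[zero])
            excluded.update(bad)
            logger.warning("tissue %s: %d genes with zero residual variance excluded", tid, len(bad))
        z = (vals - vals.mean(axis=1, keepdims=True)) / np.where(zero, np.nan, sd)[:, None]
        zf = pd.DataFrame(z, index=R.index, columns=[tis.donor_map[s] for s in R.columns])
        z_by_tissue[tid] = zf
    genes = [g for g in panel.gene_ids if g not in excluded]
    stacked = pd.concat(
        [zf.loc[genes] for zf in z_by_tissue.values()], axis=1
    )  # genes x (tissue-donor) with donor column labels
    med = stacked.T.groupby(level=0).median().T  # genes x donors
    flag_mask = (med.abs() > threshold).any(axis=1)
    flagged = set(med.index[flag_mask])
    return OutlierSet(flagged, med)
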