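"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

P_FLOOR = 1e-300


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR q)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def floor_p(p) -> np.ndarray | float:
    """Cap p-values below at P_FLOOR to avoid underflow to exact zero."""
    return np.maximum(p, P_FLOOR)
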