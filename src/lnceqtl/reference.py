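"""Bundled reference tabulations used in worked examples.

``BRAIN_LNCRNA_SUBTYPE_COUNTS`` is a published census of array-quantified
human brain lncRNAs by Ensembl subtype; it serves as input for the subtype
composition arithmetic (totals and percentage shares) and as a realistic
biotype frequency reference for the synthetic generator.
"""

from __future__ import annotations

BRAIN_LNCRNA_SUBTYPE_COUNTS: dict[str, int] = {
    "lincRNA": 6222,
    "antisense": 4141,
    "sense_intronic": 693,
    "processed": 376,
    "sense_overlapping": 154,
    "macro": 1,
}


def subtype_composition(counts: dict[str, int] | None = None) -> dict:
    """Total and per-subtype percentage shares (rounded to two decimals).

    With no argument, uses the bundled brain lncRNA census.
    """
    counts = dict(BRAIN_LNCRNA_SUBTYPE_COUNTS if counts is None else counts)
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty census")
    pct = {k: round(100.0 * v / total, 2) for k, v in counts.items()}
    return {"total": total, "percent": pct}
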