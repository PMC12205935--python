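"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package; on-disk
BED is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LNC_BIOTYPES = (
    "lincRNA",
    "antisense",
    "sense_intronic",
    "processed",
    "sense_overlapping",
    "macro",
)
CODING_BIOTYPE = "protein_coding"


@dataclass
class GeneModel:
    """A gene with strand-aware TSS and sorted, non-overlapping exons.

    ``cds`` is the coding interval (1-based inclusive) for protein-coding
    genes and ``None`` for non-coding biotypes; exon parts outside the CDS
    are the UTRs.
    """

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = exons
        expected_tss = exons[0][0] if self.strand == "+" else exons[-1][1]
        if self.tss != expected_tss:
            raise ValueError(
                f"{self.gene_id}: TSS {self.tss} inconsistent with strand "
                f"{self.strand} (expected {expected_tss})"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    @property
    def is_coding(self) -> bool:
        return self.biotype == CODING_BIOTYPE


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix plus a variant table.

    ``dosages`` holds allele counts in {0,1,2}; ``variants`` has columns
    (variant_id, chrom, pos, maf_observed) with positions strictly
    increasing within a chromosome.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples x variants")
        self.variants = self.variants.reset_index(drop=True)
        self._col = {v: i for i, v in enumerate(self.variants["variant_id"])}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column_index(self, variant_id: str) -> int:
        try:
            return self._col[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} absent from genotype matrix")

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.column_index(variant_id)].astype(float)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.samples)}
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(self.dosages[rows], self.variants.copy(), list(sample_ids))


@dataclass
class TissueExpression:
    """One tissue's genes x samples matrix (log2 scale) with donor mapping."""

    tissue_id: str
    matrix: pd.DataFrame  # genes x samples
    donor_map: dict[str, str]  # sample id -> donor id

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def donors(self) -> list[str]:
        return [self.donor_map[s] for s in self.matrix.columns]


@dataclass
class ExpressionPanel:
    """Per-tissue expression matrices sharing donor covariates."""

    tissues: dict[str, TissueExpression]
    gene_ids: list[str]
    covariates: pd.DataFrame  # donors x (age, sex)

    def __post_init__(self) -> None:
        for t in self.tissues.values():
            if list(t.matrix.index) != list(self.gene_ids):
                raise ValueError(f"tissue {t.tissue_id}: gene ids differ from panel")

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.tissues)


@dataclass
class GroundTruth:
    """Bookkeeping of every simulated nonzero effect."""

    true_effects: dict[tuple[str, str, str], float]  # (gene, variant, tissue) -> beta
    causal_pairs: dict[tuple[str, str], float]  # (lnc, mrna) -> theta
    confounder_loadings: dict[str, float]
    factor_scores: pd.DataFrame  # donors x factors

    def effect_genes(self) -> set[str]:
        return {g for g, _, _ in self.true_effects}

    def effect_variants(self) -> set[str]:
        return {v for _, v, _ in self.true_effects}


@dataclass
class GwasSummary:
    """Per-variant marginal association summary statistics."""

    table: pd.DataFrame  # variant_id, z, beta, se, n

    def __post_init__(self) -> None:
        need = {"variant_id", "z", "beta", "se", "n"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS summary missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    def z_for(self, variant_ids: list[str]) -> np.ndarray:
        s = self.table.set_index("variant_id")["z"]
        return s.loc[list(variant_ids)].to_numpy(float)


@dataclass
class AnnotationBundle:
    """Functional intervals, TF peak sets and disease variant sets."""

    functional_intervals: pd.DataFrame  # chrom, start, end, label (1-based inclusive)
    tf_peaks: dict[str, pd.DataFrame]  # name -> chrom, start, end
    disease_sets: dict[str, set[str]]  # disease -> variant ids

    def __post_init__(self) -> None:
        for d, s in self.disease_sets.items():
            if not s:
                raise ValueError(f"disease set {d!r} is empty")


@dataclass
class CovariateMatrix:
    """Samples x covariates, aligned to one tissue's sample order."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(float)
        const = [
            c
            for c, v in zip(self.data.columns, vals.T)
            if np.ptp(v) == 0 and c != "intercept"
        ]
        if const:
            raise ValueError(f"constant covariate columns: {const}")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @staticmethod
    def concat(parts: list["CovariateMatrix"]) -> "CovariateMatrix":
        frames = [p.data for p in parts]
        idx = frames[0].index
        for f in frames[1:]:
            if not f.index.equals(idx):
                raise ValueError("covariate blocks not aligned on samples")
        return CovariateMatrix(pd.concat(frames, axis=1))


@dataclass
class FactorSet:
    """Hidden expression factors (scores orthogonal to known covariates)."""

    scores: pd.DataFrame  # samples x HF1..HFk
    variance_explained: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class OutlierSet:
    flagged_genes: set[str]
    median_z: pd.DataFrame  # genes x donors, median Z across tissues


@dataclass
class CisPairIndex:
    """Tested (gene, variant) pairs within the cis window."""

    pairs: pd.DataFrame  # gene_id, variant_id
    window: int
    genes_without_cis: list[str] = field(default_factory=list)

    def variants_of(self, gene_id: str) -> list[str]:
        sub = self.pairs[self.pairs["gene_id"] == gene_id]
        return list(sub["variant_id"])

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.pairs["gene_id"]))


@dataclass
class EqtlTable:
    """Nominal per-pair statistics: beta is log2 expression change per alt allele."""

    table: pd.DataFrame  # gene, variant, beta, se, t, p_nominal, n

    def min_p_per_gene(self) -> pd.Series:
        return self.table.groupby("gene")["p_nominal"].min()


@dataclass
class PermNull:
    """Per-gene permuted minimum-p vectors."""

    min_p: pd.DataFrame  # genes x n_perm
    n_perm: int
    seed: int


@dataclass
class EqtlCalls:
    """elncRNA calls, per-elncRNA eSNP sets, and the non-eSNP background."""

    genes: pd.DataFrame  # gene, min_p_obs, empirical_p, q, is_elncRNA, esnp_threshold
    esnps: dict[str, set[str]]  # elncRNA gene -> eSNP variant ids
    non_esnps: set[str] = field(default_factory=set)

    @property
    def elncrnas(self) -> set[str]:
        g = self.genes
        return set(g.loc[g["is_elncRNA"], "gene"])

    def all_esnps(self) -> set[str]:
        out: set[str] = set()
        for s in self.esnps.values():
            out |= s
        return out


@dataclass
class EnrichmentResult:
    """One 2x2-table outcome used by every enrichment scan."""

    label: str
    a: int
    b: int
    c: int
    d: int
    or_estimate: float
    ci_low: float
    ci_high: float
    p: float
    q: float | None = None

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "OR": self.or_estimate,
            "CI_low": self.ci_low,
            "CI_high": self.ci_high,
            "p": self.p,
            "q": self.q,
        }


@dataclass
class RbEstimate:
    """Cross-tissue correlation of true genetic effects, error-corrected."""

    rb: float
    se: float
    n_pairs: int
    r_e: float
    clamped: bool = False


@dataclass
class TwasModel:
    """Sparse cis prediction weights for one gene."""

    gene: str
    weights: pd.Series  # variant_id -> weight
    cv_r: float
    cv_p: float
    n_train: int
    mixing: float
    folds: int
    seed: int
    retained: bool = True


@dataclass
class CausalEstimate:
    """2SLS effect of one lncRNA on one mRNA."""

    lnc: str
    mrna: str
    beta_iv: float
    se: float
    p: float
    first_stage_F: float
    instruments: list[str]
    q: float | None = None
    tss_distance: int | None = None
    tissue: str | None = None

    @property
    def weak_instrument(self) -> bool:
        return self.first_stage_F < 10.0
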