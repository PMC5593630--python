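"""Core domain types shared by every pipeline stage.

The central container is :class:`ExpressionMatrix`, a genes-by-samples
numeric matrix with identifier-based coordinates (column order never
matters). :class:`GeneStandard` holds the tiered training standards used
to derive cell-type-specific markers, :class:`MarkerSet` the ranked output
of a derivation run, and :class:`ScoreTable` per-sample signature scores.

Per-sample clinical annotations are plain :class:`pandas.DataFrame`
objects with a documented column vocabulary (see
:func:`immunodissect.io.read_annotations`); the vocabularies and the
ordinal infiltration scale live here as module constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The four lymphocyte cell types profiled by the pipeline.
LYMPHOCYTES: tuple[str, ...] = ("Bcell", "CTL", "Th1", "Th2")

#: Cell types represented in the blood compendium (monocytes serve as an
#: additional negative class during marker derivation).
COMPENDIUM_CELL_TYPES: tuple[str, ...] = LYMPHOCYTES + ("monocyte",)

#: Ordinal infiltration scale, least to most infiltrated.
INFILTRATION_LEVELS: tuple[str, ...] = ("absent", "mild", "moderate", "severe")

ER_STATUSES = frozenset({"ER+", "ER-", "unknown"})
SUBTYPES = frozenset(
    {"basal", "HER2", "luminal A", "luminal B", "normal-like", "unknown"}
)
CAAI_STATUSES = frozenset({"positive", "negative", "unknown"})
TIMEPOINTS = frozenset({"pre", "day90", "none"})

#: Categorical annotation columns and their allowed vocabularies.
CATEGORICAL_VOCABULARIES: dict[str, frozenset] = {
    "er_status": ER_STATUSES,
    "subtype": SUBTYPES,
    "infiltration_category": frozenset(INFILTRATION_LEVELS) | {"unknown"},
    "caai_status": CAAI_STATUSES,
    "timepoint": TIMEPOINTS,
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with identifier coordinates.

    Parameters
    ----------
    data:
        DataFrame indexed by unique gene symbols, columns unique sample
        identifiers, all values numeric (normalized intensities on a
        log-like scale, or z-scores once transformed).
    is_zscored:
        True once per-gene z-transformation has been applied.
    """

    data: pd.DataFrame
    is_zscored: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty expression matrix")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        bad = [c for c in self.data.columns if not np.issubdtype(self.data[c].dtype, np.number)]
        if bad:
            raise ValueError(f"non-numeric sample columns: {bad[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset by gene symbol, preserving the requested order."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)], is_zscored=self.is_zscored)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(samples)], is_zscored=self.is_zscored)


@dataclass(frozen=True)
class GeneStandard:
    """Tiered training standard for one cell type.

    high_positives are genes unique to the cell type (high-confidence
    positives), low_positives are relevant genes shared with other cell
    types (low-confidence positives that may be promoted during
    derivation), negatives are the unique genes of the other cell types.
    """

    cell_type: str
    high_positives: frozenset[str]
    low_positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        hp = frozenset(self.high_positives)
        lp = frozenset(self.low_positives)
        ng = frozenset(self.negatives)
        object.__setattr__(self, "high_positives", hp)
        object.__setattr__(self, "low_positives", lp)
        object.__setattr__(self, "negatives", ng)
        if not hp:
            raise ValueError(f"{self.cell_type}: no high-tier positive genes")
        if not ng:
            raise ValueError(f"{self.cell_type}: no negative genes")
        if hp & lp or hp & ng or lp & ng:
            raise ValueError(f"{self.cell_type}: standard tiers are not disjoint")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.high_positives | self.low_positives | self.negatives


@dataclass
class MarkerSet:
    """Ranked cell-type-specific genes plus the selected top-N signature."""

    cell_type: str
    ranked_genes: list[tuple[str, float]]
    n_selected: int
    #: final positive training genes (flagged; still eligible for the ranking)
    training_genes: frozenset[str] = frozenset()
    #: promoted-positive set after each iteration (monotonically growing)
    promotion_history: tuple[frozenset[str], ...] = ()
    converged: bool = True

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranked_genes]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranked_genes not sorted by non-increasing score")
        if not 0 <= self.n_selected <= len(self.ranked_genes):
            raise ValueError("n_selected out of range")

    @property
    def signature(self) -> list[str]:
        return [g for g, _ in self.ranked_genes[: self.n_selected]]

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.ranked_genes)

    def with_top_n(self, n: int) -> "MarkerSet":
        if n <= 0:
            raise ValueError("n must be positive")
        if n > len(self.ranked_genes):
            raise ValueError(f"n={n} exceeds ranked list length {len(self.ranked_genes)}")
        return replace(self, n_selected=n)


@dataclass
class ScoreTable:
    """Per-sample signature scores (d_s) with the gene counts behind them."""

    scores: pd.DataFrame  # samples x signatures
    n_genes_used: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("scores contain non-finite values")
        unknown = set(self.n_genes_used) - set(self.scores.columns)
        if unknown:
            raise ValueError(f"n_genes_used for unknown signatures: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def column(self, name: str) -> pd.Series:
        return self.scores[name]

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def as_ordered_infiltration(values: Iterable) -> pd.Categorical:
    """Coerce labels onto the ordered absent<mild<moderate<severe scale.

    Unknown / missing labels become NaN codes and are dropped by ordinal
    analyses downstream.
    """
    vals = ["unknown" if pd.isna(v) else str(v) for v in values]
    bad = sorted({v for v in vals if v not in CATEGORICAL_VOCABULARIES["infiltration_category"]})
    if bad:
        raise ValueError(f"unrecognized infiltration categories: {bad}")
    cleaned = [v if v != "unknown" else None for v in vals]
    return pd.Categorical(cleaned, categories=list(INFILTRATION_LEVELS), ordered=True)
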