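"""Readers/writers for expression matrices, gene sets, annotations, and
the per-gene z-score transform shared by every stage.

Supported formats: tab-delimited matrices (gene column + sample columns),
GCT 1.2, GMT gene sets, and TSV annotation tables with the column
vocabulary documented in :mod:`immunodissect.types`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    CATEGORICAL_VOCABULARIES,
    ExpressionMatrix,
    as_ordered_infiltration,
)

logger = logging.getLogger(__name__)

ANNOTATION_NUMERIC_COLUMNS = ("survival_time", "event")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # mean-collapse, preserving first-occurrence order (order-independent result)
    if not df.index.has_duplicates:
        return df
    dups = df.index[df.index.duplicated()].unique().tolist()
    logger.warning(
        "collapsing %d duplicated gene symbol(s) by mean (e.g. %s)",
        len(dups), dups[:5],
    )
    order = list(dict.fromkeys(df.index))
    return df.groupby(level=0, sort=False).mean().loc[order]


def _validate_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in df.columns:
        if np.issubdtype(df[col].dtype, np.number):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col][coerced.isna() & df[col].notna()]
        if len(bad):
            gene = bad.index[0]
            line = list(df.index).index(gene) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"{path}: non-numeric value {bad.iloc[0]!r} for gene {gene!r} "
                f"(line {line}, column {col!r})"
            )
        df[col] = coerced
    return df


def read_expression_matrix(path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes-by-samples matrix from TSV or GCT 1.2.

    Duplicate gene rows are collapsed by mean with a logged warning.
    Gene symbols are whitespace-trimmed and matched case-sensitively.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")

    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: line 1: expected GCT header '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ParseError(f"{path}: line 2: expected '<n_genes> <n_samples>'")
            try:
                n_genes, n_samples = int(dims[0]), int(dims[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line 2: non-integer dimensions") from exc
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        elif df.shape[1] >= 1:
            df = df.drop(columns=[df.columns[0]])  # second column is description
        if df.shape != (n_genes, n_samples):
            raise ParseError(
                f"{path}: declared dimensions {n_genes}x{n_samples} do not match "
                f"body {df.shape[0]}x{df.shape[1]}"
            )
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise ParseError(f"{path}: empty matrix file") from exc

    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    df = _validate_numeric(df, path)
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df)


def write_expression_matrix(m: ExpressionMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        out = m.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(m.sample_ids) + "\n")
            for gene, row in zip(m.gene_ids, m.values):
                fh.write(gene + "\tna\t" + "\t".join("%.10g" % v for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name TAB description TAB gene [TAB gene ...] per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an annotation table in place conventions.

    Categorical columns are checked against their vocabularies (missing
    values become "unknown"); infiltration_category is stored as an
    ordered Categorical; survival_time must be non-negative and event in
    {0, 1}. Unknown columns are preserved untouched.
    """
    df = df.copy()
    if "sample_id" not in df.columns:
        raise ValueError("annotation table lacks required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"duplicate sample_id values: {dups[:5]}")

    for col, vocab in CATEGORICAL_VOCABULARIES.items():
        if col not in df.columns:
            continue
        vals = df[col].map(lambda v: "unknown" if pd.isna(v) or str(v).strip() == "" else str(v).strip())
        if col == "infiltration_category":
            df[col] = as_ordered_infiltration(vals)
            continue
        bad = sorted(set(vals) - vocab)
        if bad:
            raise ValueError(f"column {col!r}: unrecognized value(s) {bad}")
        df[col] = vals

    if "survival_time" in df.columns:
        df["survival_time"] = pd.to_numeric(df["survival_time"], errors="raise")
        if (df["survival_time"].dropna() < 0).any():
            raise ValueError("survival_time contains negative values")
    if "event" in df.columns:
        df["event"] = pd.to_numeric(df["event"], errors="raise")
        bad_ev = sorted(set(df["event"].dropna().unique()) - {0, 1})
        if bad_ev:
            raise ValueError(f"event column must be 0/1, found {bad_ev}")
    return df


def read_annotations(path) -> pd.DataFrame:
    """Read and validate a per-sample clinical annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    return validate_annotations(df)


def write_annotations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "infiltration_category" in out.columns:
        out["infiltration_category"] = (
            out["infiltration_category"].astype(object).where(
                pd.notna(out["infiltration_category"]), "unknown"
            )
        )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def zscore_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across samples: z_gs = (x_gs - mu_g) / sigma_g.

    Uses the sample standard deviation (n-1 denominator). Genes with zero
    dispersion are dropped with a logged warning rather than mapped to
    z = 0, which would fabricate signal in downstream averages.
    """
    if m.is_zscored:
        raise ValueError("matrix is already z-scored")
    if m.n_samples < 2:
        raise ValueError("z-score transform requires >=2 samples (sigma undefined)")
    mu = m.data.mean(axis=1)
    sigma = m.data.std(axis=1, ddof=1)
    constant = sigma == 0
    if constant.any():
        dropped = list(m.data.index[constant])
        logger.warning(
            "dropping %d constant gene(s) with sigma=0 (e.g. %s)",
            len(dropped), dropped[:5],
        )
    kept = m.data.loc[~constant]
    z = kept.sub(mu[~constant], axis=0).div(sigma[~constant], axis=0)
    if z.shape[0] == 0:
        raise ValueError("all genes had zero dispersion; nothing to z-score")
    return ExpressionMatrix(z, is_zscored=True)
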