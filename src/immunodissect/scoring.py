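"""Signature scoring and gene-dropout robustness.

A signature score for sample s is the mean of the z-score-transformed
expression over the signature's n genes:

    d_s = (1/n) * sum_i z_is

Genes not assayed in the matrix are excluded from the average and n is
adjusted accordingly. The total-lymphocyte score averages over the
deduplicated union of the four lymphocyte signatures. The ER activity
score uses the same formula over an ER-associated gene set; by
convention, scores below zero call a sample ER- and above zero ER+
(exactly zero is left unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, ScoreTable

logger = logging.getLogger(__name__)

#: default gene-removal grid for the robustness sweep
DEFAULT_REMOVAL_GRID: tuple[float, ...] = tuple(
    round(0.05 * i, 2) for i in range(20)
)  # 0.0 .. 0.95


def _present_genes(
    z: ExpressionMatrix, signature: Sequence[str], name: str
) -> list[str]:
    seen = dict.fromkeys(signature)  # dedup, preserve order
    present = [g for g in seen if g in z.data.index]
    if not present:
        raise ValueError(f"no genes of signature {name!r} are present in the matrix")
    n_absent = len(seen) - len(present)
    if n_absent:
        logger.info("%s: %d signature gene(s) not assayed, excluded", name, n_absent)
    return present


def signature_score(
    z: ExpressionMatrix, signature: Sequence[str], name: str = "signature"
) -> pd.Series:
    """Per-sample mean z-score over the signature genes present.

    The returned Series carries ``attrs['n_genes_used']``.
    """
    if not z.is_zscored:
        raise ValueError("matrix must be z-scored before scoring")
    present = _present_genes(z, signature, name)
    s = z.data.loc[present].mean(axis=0)
    s.name = name
    s.attrs["n_genes_used"] = len(present)
    return s


def total_lymphocyte_score(
    z: ExpressionMatrix, signatures: Mapping[str, Sequence[str]], name: str = "total"
) -> pd.Series:
    """Score over the deduplicated union of the lymphocyte signatures."""
    union: dict[str, None] = {}
    for genes in signatures.values():
        union.update(dict.fromkeys(genes))
    return signature_score(z, list(union), name=name)


def er_activity_score(
    z: ExpressionMatrix, er_signature: Sequence[str], name: str = "ER"
) -> pd.Series:
    """ER activity via the same averaging formula over the ER gene set."""
    return signature_score(z, er_signature, name=name)


def er_call(score: pd.Series) -> pd.Series:
    """Sign rule: score < 0 -> ER-, score > 0 -> ER+, exactly 0 -> unknown."""
    calls = pd.Series(
        np.where(score < 0, "ER-", np.where(score > 0, "ER+", "unknown")),
        index=score.index,
        name="er_call",
    )
    n_zero = int((score == 0).sum())
    if n_zero:
        logger.warning("%d sample(s) with ER score exactly 0 left unknown", n_zero)
    return calls


def score_table(
    z: ExpressionMatrix,
    signatures: Mapping[str, Sequence[str]],
    er_signature: Sequence[str] | None = None,
) -> ScoreTable:
    """Assemble per-signature scores plus the total (and ER, if given)."""
    cols: dict[str, pd.Series] = {}
    n_used: dict[str, int] = {}
    for name, genes in signatures.items():
        s = signature_score(z, genes, name=name)
        cols[name] = s
        n_used[name] = s.attrs["n_genes_used"]
    total = total_lymphocyte_score(z, signatures)
    cols["total"] = total
    n_used["total"] = total.attrs["n_genes_used"]
    if er_signature is not None:
        er = er_activity_score(z, er_signature)
        cols["ER"] = er
        n_used["ER"] = er.attrs["n_genes_used"]
    return ScoreTable(pd.DataFrame(cols), n_genes_used=n_used)


@dataclass
class RobustnessResult:
    """Outcome of the gene-dropout robustness sweep for one signature.

    ``table`` has one row per (fraction, repetition) with the number of
    genes removed, the recomputed Kendall tau-b against the ordered
    infiltration categories, and its p-value.
    """

    table: pd.DataFrame
    fractions: tuple[float, ...]
    reps: int
    seed: int
    alpha: float = 0.05

    @property
    def max_preserved_fraction(self) -> float | None:
        """Largest grid fraction f such that the trend is significant in
        every repetition at every grid fraction <= f (None if even the
        smallest fraction fails)."""
        best: float | None = None
        for f in sorted(self.fractions):
            sub = self.table[self.table["fraction"] == f]
            if (sub["p_value"] < self.alpha).all():
                best = f
            else:
                break
        return best


def _category_ranks(categories) -> tuple[np.ndarray, np.ndarray]:
    """Ordered categories -> integer codes; returns (mask, codes)."""
    cat = pd.Series(categories)
    if isinstance(cat.dtype, pd.CategoricalDtype) and cat.cat.ordered:
        codes = cat.cat.codes.to_numpy()
    else:
        from .types import as_ordered_infiltration

        codes = pd.Categorical(as_ordered_infiltration(cat)).codes
    mask = codes >= 0
    if len(np.unique(codes[mask])) < 2:
        raise ValueError("need >=2 represented category levels")
    return mask, codes


def robustness_analysis(
    z: ExpressionMatrix,
    signature: Sequence[str],
    categories,
    fractions: Sequence[float] = DEFAULT_REMOVAL_GRID,
    reps: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    mode: str = "fraction",
    n_remove: int = 50,
    name: str = "signature",
) -> RobustnessResult:
    """Random gene-removal sweep of the score-vs-category trend.

    In ``fraction`` mode (default), for each fraction f on the grid and
    each repetition, round(f * n) genes (at least 1 for f > 0) are
    removed without replacement, the score recomputed, and Kendall
    tau-b against the category ranks tested. ``count`` mode removes a
    fixed ``n_remove`` genes per repetition instead (the grid is then
    ignored), mirroring a fixed-size removal protocol.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    present = _present_genes(z, signature, name)
    n = len(present)

    if isinstance(categories, pd.Series) and set(z.sample_ids) <= set(categories.index):
        cats = categories.reindex(z.sample_ids)
    else:
        cats = pd.Series(categories)
        if len(cats) != z.n_samples:
            raise ValueError("categories length does not match sample count")
    mask, codes = _category_ranks(cats)

    if mode == "count":
        if not 0 < n_remove < n:
            raise ValueError(f"n_remove must be in (0, {n})")
        fractions = (n_remove / n,)
        removal_sizes = {fractions[0]: n_remove}
    elif mode == "fraction":
        fractions = tuple(float(f) for f in fractions)
        for f in fractions:
            if f < 0 or f >= 1:
                raise ValueError(f"removal fraction {f} outside [0, 1)")
        removal_sizes = {
            f: 0 if f == 0 else min(max(1, round(f * n)), n - 1) for f in fractions
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")

    zsub = z.data.loc[present].to_numpy()
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(fractions))]

    rows = []
    for f, rng in zip(fractions, rngs):
        k = removal_sizes[f]
        for rep in range(reps):
            if k == 0:
                kept = np.arange(n)
            else:
                removed = rng.choice(n, size=k, replace=False)
                kept = np.setdiff1d(np.arange(n), removed)
            scores = zsub[kept].mean(axis=0)
            tau, p = stats.kendalltau(scores[mask], codes[mask])
            rows.append(
                {
                    "fraction": f,
                    "rep": rep,
                    "n_removed": k,
                    "n_genes_used": n - k,
                    "tau": float(tau),
                    "p_value": float(p),
                }
            )
    table = pd.DataFrame(rows)
    return RobustnessResult(
        table=table, fractions=tuple(fractions), reps=reps, seed=seed, alpha=alpha
    )
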