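"""Derivation of cell-type-specific marker genes by iterative
semi-supervised classification over an expression compendium.

Genes are instances: each gene's feature vector is its (per-gene
z-scored) expression profile across the compendium samples. Starting
from tiered standards, a regularized linear classifier is trained with
the high-confidence positives against the negatives; every gene is then
scored by its signed distance to the decision boundary, low-tier
positives scoring above a quantile threshold within their tier are
promoted into the positive training class, and the classifier is
retrained until the promoted set stops changing. The final ranking by
decision score, truncated at top N (default 100), is the cell type's
marker signature.

The promotion scheme (train -> score -> promote low-tier positives ->
retrain) is this package's reading of the iterative standard-selection
idea; promotion is monotone, so with no low-tier positives (or a
promotion threshold of 1) the procedure reduces to a single supervised
fit and the ranking is the plain margin ranking of a linear model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .types import ExpressionMatrix, GeneStandard, MarkerSet

logger = logging.getLogger(__name__)

MIN_HIGH_POSITIVES = 5


@dataclass
class DerivationParams:
    """Tunables of the iterative derivation.

    C is the inverse regularization strength of the logistic model
    (sklearn convention); promotion_quantile is the decision-score
    quantile within the low tier above which low-tier positives are
    promoted each iteration.
    """

    C: float = 1.0
    max_iterations: int = 10
    promotion_quantile: float = 0.5
    cv_folds: int = 5
    top_n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.promotion_quantile < 1:
            raise ValueError("promotion_quantile must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def build_standards(
    cell_type_gene_table: dict[str, list[str]]
) -> dict[str, GeneStandard]:
    """Tier each cell type's gene list into a GeneStandard.

    high_positives: genes in no other cell type's list; low_positives:
    this type's genes appearing in at least one other list; negatives:
    union of the other types' unique genes.
    """
    if len(cell_type_gene_table) < 2:
        raise ValueError("need >=2 cell types to build standards")
    for ct, genes in cell_type_gene_table.items():
        if not genes:
            raise ValueError(f"{ct}: empty gene list")

    sets = {ct: set(genes) for ct, genes in cell_type_gene_table.items()}
    unique = {
        ct: {
            g
            for g in gs
            if not any(g in other for o, other in sets.items() if o != ct)
        }
        for ct, gs in sets.items()
    }
    no_unique = sorted(ct for ct, ug in unique.items() if not ug)
    if no_unique:
        raise ValueError(
            f"cell type(s) with zero unique genes (no high-tier positives): {no_unique}"
        )

    standards = {}
    for ct, gs in sets.items():
        negatives = set().union(*(unique[o] for o in sets if o != ct))
        standards[ct] = GeneStandard(
            cell_type=ct,
            high_positives=frozenset(unique[ct]),
            low_positives=frozenset(gs - unique[ct]),
            negatives=frozenset(negatives),
        )
    return standards


def _present_standard(
    standard: GeneStandard, genes: set[str], min_high: int = MIN_HIGH_POSITIVES
) -> tuple[list[str], list[str], list[str]]:
    high = sorted(standard.high_positives & genes)
    low = sorted(standard.low_positives & genes)
    neg = sorted(standard.negatives & genes)
    absent = standard.all_genes - genes
    if absent:
        logger.warning(
            "%s: %d standard gene(s) absent from compendium (e.g. %s)",
            standard.cell_type, len(absent), sorted(absent)[:5],
        )
    if len(high) < min_high:
        raise ValueError(
            f"{standard.cell_type}: only {len(high)} high-tier positives present "
            f"(need >= {min_high})"
        )
    if not neg:
        raise ValueError(f"{standard.cell_type}: no negative genes present")
    return high, low, neg


def _fit_scores(
    X: np.ndarray,
    train_rows: list[int],
    y: np.ndarray,
    C: float,
) -> np.ndarray:
    Xtr = X[train_rows]
    if np.all(Xtr == Xtr[0]):
        raise ValueError("degenerate training set: all feature rows identical")
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
    clf.fit(Xtr, y)
    return clf.decision_function(X)


def nanodissect(
    compendium: ExpressionMatrix,
    standard: GeneStandard,
    params: DerivationParams | None = None,
    _min_high: int = MIN_HIGH_POSITIVES,
) -> MarkerSet:
    """Run the iterative derivation for one cell type.

    Requires a per-gene z-scored compendium so decision-boundary
    distances are comparable across genes. Returns all compendium genes
    ranked by final decision score (ties broken lexicographically by
    gene symbol), with the top ``params.top_n`` genes as the signature.
    """
    params = params or DerivationParams()
    if not compendium.is_zscored:
        raise ValueError("compendium must be z-scored per gene before derivation")

    genes = compendium.gene_ids
    gene_idx = {g: i for i, g in enumerate(genes)}
    high, low, neg = _present_standard(standard, set(genes), min_high=_min_high)

    X = compendium.values
    positives: set[str] = set(high)
    low_pool: set[str] = set(low)  # low-tier genes not yet promoted
    history: list[frozenset[str]] = []
    scores = None
    converged = False

    for _it in range(params.max_iterations):
        train = sorted(positives) + neg
        train_rows = [gene_idx[g] for g in train]
        y = np.array([1] * len(positives) + [0] * len(neg))
        scores = _fit_scores(X, train_rows, y, params.C)

        promoted_now: set[str] = set()
        if low:
            low_scores = np.array([scores[gene_idx[g]] for g in low])
            threshold = np.quantile(low_scores, params.promotion_quantile)
            promoted_now = {
                g for g in low_pool if scores[gene_idx[g]] > threshold
            }
        history.append(frozenset(positives - set(high) | promoted_now))
        if not promoted_now:
            converged = True
            break
        positives |= promoted_now
        low_pool -= promoted_now

    if not converged:
        logger.warning(
            "%s: promotion did not converge within %d iterations; using last iterate",
            standard.cell_type, params.max_iterations,
        )

    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    ranked = [(genes[i], float(scores[i])) for i in order]
    n_sel = min(params.top_n, len(ranked))
    return MarkerSet(
        cell_type=standard.cell_type,
        ranked_genes=ranked,
        n_selected=n_sel,
        training_genes=frozenset(positives),
        promotion_history=tuple(history),
        converged=converged,
    )


def select_top_markers(ranked: MarkerSet, n: int) -> MarkerSet:
    """Truncate the ranked list at n, tie-breaking lexicographically."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(ranked.ranked_genes):
        raise ValueError(
            f"n={n} exceeds ranked list length {len(ranked.ranked_genes)}"
        )
    resorted = sorted(ranked.ranked_genes, key=lambda t: (-t[1], t[0]))
    return MarkerSet(
        cell_type=ranked.cell_type,
        ranked_genes=resorted,
        n_selected=n,
        training_genes=ranked.training_genes,
        promotion_history=ranked.promotion_history,
        converged=ranked.converged,
    )


def crossval_auc(
    compendium: ExpressionMatrix,
    standard: GeneStandard,
    params: DerivationParams | None = None,
) -> tuple[list[float], float]:
    """Stratified k-fold CV of the derivation over the standard genes.

    Folds are stratified over the tier structure (high / low / negative)
    so every fold holds out genes from each represented tier; the
    iterative procedure runs inside the training fold only, and AUROC is
    computed on the held-out standard genes (positives = both tiers).
    Returns (per-fold AUCs, mean AUC).
    """
    params = params or DerivationParams()
    if not compendium.is_zscored:
        raise ValueError("compendium must be z-scored per gene")
    high, low, neg = _present_standard(standard, set(compendium.gene_ids))

    genes = np.array(high + low + neg)
    tiers = np.array(["high"] * len(high) + ["low"] * len(low) + ["neg"] * len(neg))
    y = (tiers != "neg").astype(int)
    # a tier too small to stratify on its own folds with the other positives
    if 0 < len(low) < params.cv_folds:
        tiers = np.where(tiers == "low", "high", tiers)
    if y.sum() < params.cv_folds or (1 - y).sum() < params.cv_folds:
        raise ValueError("need at least cv_folds genes in each class")

    skf = StratifiedKFold(
        n_splits=params.cv_folds, shuffle=True, random_state=params.seed
    )
    fold_aucs: list[float] = []
    for train_idx, test_idx in skf.split(genes, tiers):
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("a CV fold holds out only one class")
        tr = set(genes[train_idx])
        sub = GeneStandard(
            cell_type=standard.cell_type,
            high_positives=frozenset(g for g in high if g in tr),
            low_positives=frozenset(g for g in low if g in tr),
            negatives=frozenset(g for g in neg if g in tr),
        )
        # the >=5 high-positive floor applies to the full standard, checked
        # above; training folds may legitimately hold fewer
        ms = nanodissect(compendium, sub, params, _min_high=1)
        score_of = ms.scores
        test_scores = [score_of[g] for g in genes[test_idx]]
        fold_aucs.append(float(roc_auc_score(y[test_idx], test_scores)))
    return fold_aucs, float(np.mean(fold_aucs))


def derive_all(
    compendium: ExpressionMatrix,
    standards: dict[str, GeneStandard],
    params: DerivationParams | None = None,
) -> dict[str, MarkerSet]:
    """Run the derivation for every cell type in ``standards``."""
    return {ct: nanodissect(compendium, std, params) for ct, std in standards.items()}
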