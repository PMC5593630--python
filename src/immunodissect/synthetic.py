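"""Synthetic compendia and tumor cohorts with the statistical structure
the analysis assumes, providing ground truth for every downstream stage.

Two generators:

* :func:`generate_compendium` — a blood expression compendium in which
  each of five immune cell types (B cell, CTL, Th1, Th2, monocyte) has a
  co-expressed gene program that is up-shifted in the samples where the
  cell type is active. Only the two T-helper programs share genes.
  Tiered training standards are built from sampled seed genes.

* :func:`generate_tumor_cohort` — bulk tumor profiles modelled as a
  baseline plus an estrogen-receptor (ER) program scaled by a latent ER
  activity, plus immune programs weighted by per-sample infiltration
  fractions. Infiltration is anti-correlated with ER activity, reduced
  in genomically unstable (CAAI+) samples, protective for survival only
  in the ER- stratum, and increased at the second timepoint of paired
  pre/post-treatment biopsies.

All generators are pure functions of their config including the seed:
a single :class:`numpy.random.SeedSequence` is split deterministically
per sub-task, so enlarging one dimension does not perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    COMPENDIUM_CELL_TYPES,
    ExpressionMatrix,
    GeneStandard,
    INFILTRATION_LEVELS,
    LYMPHOCYTES,
)
from . import io as iom


def _gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


@dataclass
class CompendiumConfig:
    """Configuration of the synthetic blood compendium."""

    n_samples: int = 400
    n_genes: int = 4000
    cell_types: tuple[str, ...] = COMPENDIUM_CELL_TYPES
    genes_per_program: int = 120
    #: genes shared between the Th1 and Th2 programs (the only overlap)
    overlap_th1_th2: int = 30
    #: mean log-intensity shift of a program gene in active samples
    program_effect: float = 2.0
    noise_sd: float = 1.0
    #: probability that a cell type is active in a given sample
    active_prob: float = 0.3
    #: seed genes sampled from each true program to build the standards
    seeds_per_program: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = tuple(self.cell_types)
        if self.overlap_th1_th2 >= self.genes_per_program:
            raise ValueError("overlap_th1_th2 must be smaller than genes_per_program")
        span = (
            len(self.cell_types) * self.genes_per_program - self.overlap_th1_th2
        )
        if span > self.n_genes:
            raise ValueError(
                f"programs need {span} genes but the universe has only {self.n_genes}"
            )
        if self.seeds_per_program > self.genes_per_program:
            raise ValueError("seeds_per_program exceeds genes_per_program")
        if not 0 <= self.active_prob <= 1:
            raise ValueError("active_prob must be in [0, 1]")


def _program_layout(cfg: CompendiumConfig) -> dict[str, list[str]]:
    """Assign contiguous gene blocks to programs; Th1/Th2 share a block."""
    genes = _gene_universe(cfg.n_genes)
    programs: dict[str, list[str]] = {}
    cursor = 0
    for ct in cfg.cell_types:
        if ct == "Th2" and "Th1" in programs:
            shared = programs["Th1"][-cfg.overlap_th1_th2 :]
            fresh = genes[cursor : cursor + cfg.genes_per_program - cfg.overlap_th1_th2]
            cursor += cfg.genes_per_program - cfg.overlap_th1_th2
            programs[ct] = shared + fresh
        else:
            programs[ct] = genes[cursor : cursor + cfg.genes_per_program]
            cursor += cfg.genes_per_program
    return programs


def build_standards_from_programs(
    programs: Mapping[str, Sequence[str]],
    seeds_per_program: int,
    rng: np.random.Generator,
) -> dict[str, GeneStandard]:
    """Sample seed genes per program and tier them into a GeneStandard.

    Seed genes unique to the cell type (relative to the *true* programs)
    become high-tier positives; seeds shared with another program become
    low-tier positives; negatives are the union of the other cell types'
    unique seed genes.
    """
    seeds: dict[str, list[str]] = {}
    for ct in programs:
        pool = list(programs[ct])
        k = min(seeds_per_program, len(pool))
        seeds[ct] = sorted(rng.choice(pool, size=k, replace=False).tolist())

    membership: dict[str, set[str]] = {}
    for ct, genes in programs.items():
        for g in genes:
            membership.setdefault(g, set()).add(ct)

    unique_seeds = {
        ct: [g for g in seeds[ct] if membership[g] == {ct}] for ct in programs
    }
    standards: dict[str, GeneStandard] = {}
    for ct in programs:
        high = unique_seeds[ct]
        low = [g for g in seeds[ct] if len(membership[g]) > 1]
        neg = sorted(
            {g for other, ug in unique_seeds.items() if other != ct for g in ug}
        )
        standards[ct] = GeneStandard(
            cell_type=ct,
            high_positives=frozenset(high),
            low_positives=frozenset(low),
            negatives=frozenset(neg),
        )
    return standards


def generate_compendium(
    cfg: CompendiumConfig,
) -> tuple[ExpressionMatrix, dict[str, list[str]], dict[str, GeneStandard]]:
    """Simulate the blood compendium.

    Returns the raw (not yet z-scored) expression matrix, the map of
    true program genes per cell type, and a tiered GeneStandard per cell
    type built from sampled seed genes.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_noise, rng_activity, rng_seeds = (np.random.default_rng(s) for s in ss.spawn(3))

    programs = _program_layout(cfg)
    genes = _gene_universe(cfg.n_genes)
    samples = [f"C{i:04d}" for i in range(cfg.n_samples)]

    x = rng_noise.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    for ct in cfg.cell_types:
        active = rng_activity.random(cfg.n_samples) < cfg.active_prob
        rows = [gene_index[g] for g in programs[ct]]
        x[np.ix_(rows, np.flatnonzero(active))] += cfg.program_effect

    matrix = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))
    standards = build_standards_from_programs(programs, cfg.seeds_per_program, rng_seeds)
    return matrix, programs, standards


@dataclass
class TumorCohortConfig:
    """Configuration of the synthetic tumor cohort.

    The latent ER activity a_s ~ N(0,1) drives both the ER expression
    program and the mean of the Beta-distributed infiltration fractions,
    which decreases linearly with a_s (slope `er_slope`, calibrated so
    that ER activity and total infiltration correlate at r ~ -0.4).
    Survival is exponential with log-hazard b0 + b1 * total_fraction,
    with b1 < 0 (protective infiltration) only in the ER- stratum.
    """

    n_samples: int = 300
    n_genes: int = 4000
    er_program_size: int = 50
    #: fraction of ER+ samples (large breast-cancer cohorts run ~24% ER-)
    er_positive_frac: float = 0.76
    #: baseline mean infiltration fraction per cell type
    f_base: float = 0.2
    #: decrease of the Beta mean per unit of latent ER activity
    er_slope: float = 0.045
    #: Beta concentration (alpha + beta); lower = wider fraction spread
    beta_concentration: float = 4.0
    caai_positive_frac: float = 0.15
    #: multiplicative infiltration reduction in CAAI+ samples
    caai_reduction: float = 0.5
    #: baseline log-hazard of the exponential survival model
    b0: float = -2.0
    b1_er_neg: float = -1.5
    b1_er_pos: float = 0.0
    #: exponential censoring rate (~12% censoring at the defaults)
    censoring_rate: float = 0.01
    #: paired pre/day-90 biopsies appended to the cohort (58 samples)
    n_pairs: int = 29
    treatment_uplift: float = 1.4
    #: expression shift per unit infiltration fraction on program genes
    infiltration_effect: float = 4.0
    #: expression shift per unit latent ER activity on ER program genes
    er_effect: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.er_positive_frac < 1:
            raise ValueError("er_positive_frac must be in (0, 1)")
        if self.caai_reduction <= 0 or self.caai_reduction > 1:
            raise ValueError("caai_reduction must be in (0, 1]")
        if self.treatment_uplift <= 0:
            raise ValueError("treatment_uplift must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")


class TumorCohort(NamedTuple):
    """Expression + ground-truth annotations + planted ER program genes."""

    expression: ExpressionMatrix
    annotations: pd.DataFrame
    er_program: list[str]


def _beta_fractions(
    mean: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    m = np.clip(mean, 0.02, 0.9)
    return rng.beta(m * concentration, (1.0 - m) * concentration)


def generate_tumor_cohort(
    cfg: TumorCohortConfig, signatures: Mapping[str, Sequence[str]]
) -> TumorCohort:
    """Simulate a bulk tumor cohort carrying the planted immune programs.

    ``signatures`` maps each lymphocyte cell type to the genes of its
    planted program (typically the true compendium programs). All genes
    must lie inside the cohort's gene universe.
    """
    genes = _gene_universe(cfg.n_genes)
    gene_set = set(genes)
    missing = sorted(
        {g for gs in signatures.values() for g in gs if g not in gene_set}
    )
    if missing:
        raise ValueError(f"signature genes outside the gene universe: {missing[:10]}")
    cell_types = list(signatures)

    used = {g for gs in signatures.values() for g in gs}
    free = [g for g in reversed(genes) if g not in used]
    if len(free) < cfg.er_program_size:
        raise ValueError("not enough free genes for the ER program")
    er_program = sorted(free[: cfg.er_program_size])

    ss = np.random.SeedSequence(cfg.seed)
    (rng_latent, rng_frac, rng_surv, rng_noise, rng_pairs) = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n = cfg.n_samples
    a = rng_latent.normal(0.0, 1.0, size=n)
    er_threshold = stats.norm.ppf(1.0 - cfg.er_positive_frac)
    er_pos = a > er_threshold
    caai_pos = rng_latent.random(n) < cfg.caai_positive_frac

    fractions = np.empty((len(cell_types), n))
    for i, _ct in enumerate(cell_types):
        fractions[i] = _beta_fractions(
            cfg.f_base - cfg.er_slope * a, cfg.beta_concentration, rng_frac
        )
    fractions[:, caai_pos] *= cfg.caai_reduction
    total_f = fractions.sum(axis=0)

    # survival: exponential, log-hazard b0 + b1(ER stratum) * total fraction
    b1 = np.where(er_pos, cfg.b1_er_pos, cfg.b1_er_neg)
    hazard = np.exp(cfg.b0 + b1 * total_f)
    t_event = rng_surv.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        t_cens = rng_surv.exponential(1.0 / cfg.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    # subtype consistent with ER status
    subtype = np.empty(n, dtype=object)
    u = rng_latent.random(n)
    subtype[er_pos] = np.where(u[er_pos] < 0.6, "luminal A", "luminal B")
    neg = ~er_pos
    subtype[neg] = np.where(
        u[neg] < 0.5, "basal", np.where(u[neg] < 0.8, "HER2", "normal-like")
    )

    # paired pre/day-90 treatment biopsies from ER+ patients
    n_pairs = cfg.n_pairs
    if n_pairs > 0:
        lo = stats.norm.cdf(er_threshold)
        a_pair = stats.norm.ppf(rng_pairs.uniform(lo, 1.0, size=n_pairs))
        f_pre = np.empty((len(cell_types), n_pairs))
        for i, _ct in enumerate(cell_types):
            f_pre[i] = _beta_fractions(
                cfg.f_base - cfg.er_slope * a_pair, cfg.beta_concentration, rng_pairs
            )
        f_post = np.minimum(f_pre * cfg.treatment_uplift, 1.0)
    else:
        a_pair = np.empty(0)
        f_pre = f_post = np.empty((len(cell_types), 0))

    all_a = np.concatenate([a, a_pair, a_pair])
    all_fracs = np.concatenate([fractions, f_pre, f_post], axis=1)
    n_total = n + 2 * n_pairs

    sample_ids = (
        [f"S{i:04d}" for i in range(n)]
        + [f"P{i:03d}_pre" for i in range(n_pairs)]
        + [f"P{i:03d}_d90" for i in range(n_pairs)]
    )
    patient_ids = (
        [f"T{i:04d}" for i in range(n)]
        + [f"P{i:03d}" for i in range(n_pairs)] * 2
    )

    gene_index = {g: i for i, g in enumerate(genes)}
    x = rng_noise.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_total))
    er_rows = [gene_index[g] for g in er_program]
    x[er_rows, :] += cfg.er_effect * all_a
    for i, ct in enumerate(cell_types):
        rows = [gene_index[g] for g in signatures[ct]]
        x[rows, :] += cfg.infiltration_effect * all_fracs[i]

    # ordinal infiltration categories from fixed quartile cuts of total fraction
    all_total = all_fracs.sum(axis=0)
    cuts = np.quantile(all_total, [0.25, 0.5, 0.75])
    cat_idx = np.searchsorted(cuts, all_total, side="right")
    categories = [INFILTRATION_LEVELS[i] for i in cat_idx]

    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": patient_ids,
            "er_status": ["ER+" if v else "ER-" for v in np.concatenate(
                [er_pos, np.ones(2 * n_pairs, dtype=bool)]
            )],
            "subtype": np.concatenate(
                [subtype, np.full(2 * n_pairs, "luminal A", dtype=object)]
            ),
            "infiltration_category": categories,
            "caai_status": np.concatenate(
                [
                    np.where(caai_pos, "positive", "negative"),
                    np.full(2 * n_pairs, "unknown", dtype=object),
                ]
            ),
            "survival_time": np.concatenate([time, np.full(2 * n_pairs, np.nan)]),
            "event": np.concatenate([event.astype(float), np.full(2 * n_pairs, np.nan)]),
            "timepoint": (
                ["none"] * n + ["pre"] * n_pairs + ["day90"] * n_pairs
            ),
            "er_activity_latent": all_a,
            "true_total_fraction": all_total,
        }
    )
    for i, ct in enumerate(cell_types):
        ann[f"true_fraction_{ct}"] = all_fracs[i]
    ann = iom.validate_annotations(ann)

    matrix = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=sample_ids))
    return TumorCohort(matrix, ann, er_program)


def generate_toy_fixtures(outdir) -> dict[str, Path]:
    """Write tiny hand-verifiable fixtures (matrix, annotations, GMT).

    The matrix deliberately contains the row (1, 2, 3), whose z-scores
    are (-1, 0, 1) with the n-1 denominator, and a constant row that the
    transform must drop. The 6-subject survival table supports a
    hand-worked two-group log-rank calculation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    expr = pd.DataFrame(
        {
            "s1": [1.0, -1.0, 5.0, 0.0],
            "s2": [2.0, 1.0, 5.0, -1.0],
            "s3": [3.0, 0.0, 5.0, 1.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    paths["expression"] = outdir / "toy_expression.tsv"
    write = expr.copy()
    write.index.name = "gene"
    write.to_csv(paths["expression"], sep="\t")

    ann = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(1, 7)],
            "patient_id": [f"p{i}" for i in range(1, 7)],
            "er_status": ["ER-", "ER-", "ER-", "ER+", "ER+", "ER+"],
            "infiltration_category": [
                "absent", "mild", "moderate", "severe", "mild", "severe",
            ],
            "survival_time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 0],
            "timepoint": ["none"] * 6,
            "group": ["A", "A", "A", "B", "B", "B"],
        }
    )
    paths["annotations"] = outdir / "toy_annotations.tsv"
    ann.to_csv(paths["annotations"], sep="\t", index=False)

    paths["gmt"] = outdir / "toy_sets.gmt"
    iom.write_gmt({"SET1": ["gA", "gB"], "SET2": ["gC", "gD"]}, paths["gmt"])
    return paths
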