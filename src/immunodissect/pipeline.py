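"""End-to-end orchestration: synthesize -> derive -> score -> robustness
-> associate, with a reproducibility manifest.

A run is a pure function of its configuration (including the master
seed): identical config + seed produces byte-identical output tables.
Stage seeds are derived deterministically from the master seed; the
manifest records the full config, the seeds used, the package version,
and a content hash of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as iom
from .associations import SuiteConfig, run_association_suite
from .markers import DerivationParams, derive_all
from .scoring import DEFAULT_REMOVAL_GRID, robustness_analysis, score_table
from .synthetic import CompendiumConfig, TumorCohortConfig, generate_compendium, generate_tumor_cohort
from .types import LYMPHOCYTES

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run"
    compendium: CompendiumConfig = field(default_factory=CompendiumConfig)
    cohort: TumorCohortConfig | None = field(default_factory=TumorCohortConfig)
    derivation: DerivationParams = field(default_factory=DerivationParams)
    cell_types: tuple[str, ...] = LYMPHOCYTES
    robustness_fractions: tuple[float, ...] = DEFAULT_REMOVAL_GRID
    robustness_reps: int = 50
    analyses: tuple[str, ...] | None = None
    #: real-input overrides; when set, the synthetic stage is skipped
    cohort_matrix_path: str | None = None
    cohort_annotations_path: str | None = None
    write_expression: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "compendium" in kwargs:
            kwargs["compendium"] = CompendiumConfig(**kwargs["compendium"])
        if kwargs.get("cohort") is not None:
            kwargs["cohort"] = TumorCohortConfig(**kwargs["cohort"])
        if "derivation" in kwargs:
            kwargs["derivation"] = DerivationParams(**kwargs["derivation"])
        for key in ("cell_types", "robustness_fractions", "analyses"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def demo_config(outdir: str = "demo_run", seed: int = 0) -> PipelineConfig:
    """A scaled-down configuration that completes in well under a minute."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        compendium=CompendiumConfig(
            n_samples=120, n_genes=800, genes_per_program=40,
            overlap_th1_th2=10, seeds_per_program=16, seed=seed,
        ),
        cohort=TumorCohortConfig(
            n_samples=120, n_genes=800, er_program_size=20, n_pairs=12, seed=seed,
        ),
        derivation=DerivationParams(top_n=30, seed=seed),
        robustness_fractions=(0.0, 0.25, 0.5),
        robustness_reps=10,
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Outputs: markers.gmt, ranked_<celltype>.tsv, scores.tsv,
    annotations.tsv, robustness.tsv, associations.tsv, manifest.yaml.
    Stages whose inputs are unavailable (e.g. no annotations) are
    skipped with a logged reason, never silently.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seeds = {
        "compendium": cfg.seed,
        "cohort": cfg.seed + 1,
        "derivation": cfg.seed + 2,
        "robustness": cfg.seed + 3,
    }

    @_stage("synthesize_compendium")
    def s1():
        ccfg = dataclasses.replace(cfg.compendium, seed=seeds["compendium"])
        return generate_compendium(ccfg)

    compendium, programs, standards = s1()

    @_stage("derive")
    def s2():
        z = iom.zscore_transform(compendium)
        params = dataclasses.replace(cfg.derivation, seed=seeds["derivation"])
        wanted = {ct: standards[ct] for ct in cfg.cell_types}
        return derive_all(z, wanted, params)

    markers = s2()
    gmt_path = outdir / "markers.gmt"
    iom.write_gmt({ct: ms.signature for ct, ms in markers.items()}, gmt_path)
    written.append(gmt_path)
    for ct, ms in markers.items():
        p = outdir / f"ranked_{ct}.tsv"
        pd.DataFrame(ms.ranked_genes, columns=["gene", "score"]).to_csv(
            p, sep="\t", index=False, float_format="%.10g"
        )
        written.append(p)

    @_stage("cohort")
    def s3():
        if cfg.cohort_matrix_path:
            matrix = iom.read_expression_matrix(cfg.cohort_matrix_path)
            ann = (
                iom.read_annotations(cfg.cohort_annotations_path)
                if cfg.cohort_annotations_path
                else None
            )
            return matrix, ann, None
        if cfg.cohort is None:
            return None, None, None
        tcfg = dataclasses.replace(cfg.cohort, seed=seeds["cohort"])
        cohort = generate_tumor_cohort(tcfg, {ct: programs[ct] for ct in cfg.cell_types})
        return cohort.expression, cohort.annotations, cohort.er_program

    matrix, annotations, er_program = s3()
    if matrix is None:
        logger.info("no cohort configured; stopping after derivation")
        _write_manifest(cfg, seeds, written, outdir)
        return outdir

    @_stage("score")
    def s4():
        z = iom.zscore_transform(matrix)
        sigs = {ct: ms.signature for ct, ms in markers.items()}
        return z, score_table(z, sigs, er_signature=er_program)

    z_cohort, scores = s4()
    scores_path = outdir / "scores.tsv"
    scores.to_tsv(scores_path)
    written.append(scores_path)
    if cfg.write_expression:
        p = outdir / "cohort_expression.tsv"
        iom.write_expression_matrix(matrix, p)
        written.append(p)

    if annotations is None:
        logger.info("no annotations available; skipping robustness and association stages")
        _write_manifest(cfg, seeds, written, outdir)
        return outdir
    ann_path = outdir / "annotations.tsv"
    iom.write_annotations(annotations, ann_path)
    written.append(ann_path)

    @_stage("robustness")
    def s5():
        cats = annotations.set_index("sample_id")["infiltration_category"]
        frames = []
        for ct, ms in markers.items():
            res = robustness_analysis(
                z_cohort, ms.signature, cats,
                fractions=cfg.robustness_fractions, reps=cfg.robustness_reps,
                seed=seeds["robustness"], name=ct,
            )
            t = res.table.copy()
            t.insert(0, "signature", ct)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    if "infiltration_category" in annotations.columns:
        rob = s5()
        rob_path = outdir / "robustness.tsv"
        rob.to_csv(rob_path, sep="\t", index=False, float_format="%.10g")
        written.append(rob_path)
    else:
        logger.info("skipping robustness: no infiltration_category column")

    @_stage("associate")
    def s6():
        sigs = {ct: ms.signature for ct, ms in markers.items()}
        suite_cfg = SuiteConfig(analyses=cfg.analyses) if cfg.analyses else SuiteConfig()
        return run_association_suite(
            z_cohort, annotations, sigs, er_signature=er_program, config=suite_cfg
        )

    report = s6()
    rep_path = outdir / "associations.tsv"
    report.to_csv(rep_path, sep="\t", index=False, float_format="%.10g")
    written.append(rep_path)

    _write_manifest(cfg, seeds, written, outdir)
    return outdir


def _write_manifest(cfg: PipelineConfig, seeds: dict, written: list[Path], outdir: Path) -> None:
    manifest = {
        "package": "immunodissect",
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "config": cfg.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
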