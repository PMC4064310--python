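"""End-to-end orchestration: simulate -> screen -> normalize -> search -> rank.

Mirrors a two-cohort biomarker study design: a test cohort is screened
univariately for candidate genes, an independent validation cohort is
measured by qPCR on those candidates, and the panel search plus LOOCV /
ROC evaluation run on the validation cohort's normalized expression.
Every stage writes plain TSV/JSON artifacts; a manifest records the
parameters, seeds, and a hash of every output, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .cohortsim import (
    DEFAULT_CT_OFFSET,
    DEFAULT_HOUSEKEEPING,
    SimulationConfig,
    load_clinical_fixture,
    simulate_clinical_covariates,
    simulate_ct_table,
    simulate_expression_cohort,
    write_truth_genes,
)
from .cva_lda import DEFAULT_RIDGE
from .datamodel_io import (
    ConfigError,
    write_annotations,
    write_ct_table,
    write_expression_matrix,
    write_panel_report,
)
from .evaluation import rank_genes_by_panel_membership, write_ranking
from .panel_search import SEARCH_METRICS, SELECTION_MODELS, search_panels
from .preprocess import (
    comparative_ct_normalize,
    differential_genes,
    low_intensity_filter,
    univariate_table,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Parameters for one full pipeline run.

    Defaults follow the study design the pipeline emulates: lowest 20%
    intensity filter, Mann-Whitney screen at alpha 0.05 with fold-change
    cutoff 1.5, comparative-Ct normalization to PPIA, and gene ranking
    over panels with LOOCV accuracy above 80%.
    """

    seed: int = 0
    out_dir: str = "results"
    test_cohort: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(n_responders=14, n_nonresponders=6,
                                                 cohort="test"))
    validation_cohort: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(n_responders=13, n_nonresponders=7,
                                                 cohort="validation"))
    housekeeping: tuple[str, ...] = DEFAULT_HOUSEKEEPING
    ct_noise_sd: float = 0.25
    ct_offset: float = DEFAULT_CT_OFFSET
    filter_fraction: float = 0.2
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    reference_gene: str = "PPIA"
    models: tuple[str, ...] = SELECTION_MODELS
    n_restarts: int = 100
    metric: str = "resubstitution"
    ridge: float = DEFAULT_RIDGE
    cv_threshold: float = 80.0
    single_cohort: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.filter_fraction < 1.0:
            raise ConfigError("filter_fraction must lie in [0, 1)")
        if self.fc_cutoff < 1.0:
            raise ConfigError("fc_cutoff must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError("alpha must lie in (0, 1]")
        if not 0.0 <= self.cv_threshold <= 100.0:
            raise ConfigError("cv_threshold must lie in [0, 100]")
        if self.metric not in SEARCH_METRICS:
            raise ConfigError(f"unknown search metric {self.metric!r}")
        unknown = sorted(set(self.models) - set(SELECTION_MODELS))
        if unknown:
            raise ConfigError(f"unknown selection model(s): {unknown}")
        if self.reference_gene not in self.housekeeping:
            raise ConfigError("reference_gene must be one of the housekeeping genes")
        if self.test_cohort.n_genes != self.validation_cohort.n_genes:
            raise ConfigError("both cohorts must share one gene universe")
        object.__setattr__(self, "models", tuple(self.models))
        object.__setattr__(self, "housekeeping", tuple(self.housekeeping))


def config_from_dict(doc: dict) -> RunConfig:
    doc = dict(doc)
    for key in ("test_cohort", "validation_cohort"):
        if key in doc and isinstance(doc[key], dict):
            doc[key] = SimulationConfig(**doc[key])
    return RunConfig(**doc)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute every stage; return the manifest (also written to disk).

    Cohort seeds are derived from the global seed (test = seed,
    validation = seed + 1) so the two cohorts are independent draws of
    one gene universe.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "configure"
    t0 = time.perf_counter()

    def tick(name: str) -> None:
        nonlocal stage
        log(f"[{time.perf_counter() - t0:7.2f}s] stage {stage} done; starting {name}")
        stage = name

    try:
        tick("simulate")
        test_cfg = dataclasses.replace(config.test_cohort, seed=config.seed)
        val_cfg = dataclasses.replace(config.validation_cohort, seed=config.seed + 1)
        test = simulate_expression_cohort(test_cfg)
        validation = test if config.single_cohort else simulate_expression_cohort(val_cfg)
        fixture = load_clinical_fixture(test_cfg.disease)
        annotations = simulate_clinical_covariates(
            test.annotations + (() if config.single_cohort else validation.annotations),
            fixture, seed=config.seed)
        outputs["test_expression"] = out / "test_expression.tsv"
        write_expression_matrix(test.expression, outputs["test_expression"])
        outputs["annotations"] = out / "annotations.tsv"
        write_annotations(annotations, outputs["annotations"])
        outputs["truth_genes"] = out / "truth_genes.tsv"
        write_truth_genes(test.truth, outputs["truth_genes"])

        tick("filter")
        filtered = low_intensity_filter(test.expression, config.filter_fraction)

        tick("screen")
        results = differential_genes(filtered, test.labels,
                                     fc_cutoff=config.fc_cutoff, alpha=config.alpha)
        outputs["univariate"] = out / "univariate_screen.tsv"
        univariate_table(results).to_csv(outputs["univariate"], sep="\t",
                                         index=False, float_format="%.6g")
        screened = [r.gene_id for r in results if r.passed]
        log(f"  screened genes: {len(screened)} of {filtered.n_genes}")
        if len(screened) < 2:
            raise ConfigError("fewer than 2 genes passed the univariate screen")

        tick("normalize")
        val_screened = dataclasses.replace(
            validation,
            expression=validation.expression.subset_genes(sorted(screened)),
            truth=tuple(g for g in validation.truth if g in set(screened)),
        )
        ct = simulate_ct_table(val_screened, housekeeping=config.housekeeping,
                               ct_noise_sd=config.ct_noise_sd, ct_offset=config.ct_offset)
        outputs["ct_table"] = out / "validation_ct.tsv"
        write_ct_table(ct, outputs["ct_table"])
        relative = comparative_ct_normalize(ct, config.reference_gene).drop_incomplete_genes()
        outputs["validation_expression"] = out / "validation_relative_expression.tsv"
        write_expression_matrix(relative, outputs["validation_expression"])

        tick("search")
        panels = search_panels(relative, validation.labels, models=config.models,
                               n_restarts=config.n_restarts, metric=config.metric,
                               seed=config.seed, ridge=config.ridge)
        log(f"  unique panels: {len(panels)}; "
            f"best search accuracy {max(p.search_accuracy for p in panels):.1f}%")

        tick("rank")
        ranking = rank_genes_by_panel_membership(panels, cv_threshold=config.cv_threshold)
        outputs["panel_report"] = out / "panel_report.json"
        write_panel_report(panels, ranking, outputs["panel_report"])
        outputs["ranking"] = out / "gene_ranking.tsv"
        write_ranking(ranking, outputs["ranking"])

        tick("manifest")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": _jsonable(config),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                        for k, p in sorted(outputs.items())},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                                 encoding="utf-8")
        log(f"[{time.perf_counter() - t0:7.2f}s] pipeline complete; "
            f"manifest at {manifest_path}")
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
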