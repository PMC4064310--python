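"""Synthetic patient cohorts with the statistical structure the analysis assumes.

The generator emulates a two-cohort infliximab-response study: a
gene x sample expression matrix on the linear intensity scale (multivariate
normal on log2, exponentiated), a TaqMan-style Ct readout of the same
cohort with stable housekeeping assays, and baseline clinical covariates
drawn truncated-normal around published per-group summary statistics.

Model:
  log2 x[g, s] = m[g] + delta[g] * 1{s responder} + log2_sd * z[g, s]

with per-gene baseline abundances m[g] ~ N(base_log2_mean, gene_level_sd)
shared by both groups (real transcript abundances span orders of
magnitude, which is what the low-intensity filter acts on), where
``delta[g] = +/- effect_size * log2_sd`` for informative genes (sign
alternating, since real panels mix up- and down-regulated genes) and 0
otherwise, and ``z`` is standard normal with exchangeable correlation
``block_correlation`` inside each consecutive block of ``block_size``
informative genes.  Noise genes are independent.

All draws are pure functions of (config, seed); each stage uses its own
named substream so adding a stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from ._rng import substream
from .datamodel_io import (
    NONRESPONDER,
    RESPONDER,
    ConfigError,
    CtTable,
    ExpressionMatrix,
    SampleAnnotation,
)

import pandas as pd

#: Default Ct at unit linear expression (cycles).
DEFAULT_CT_OFFSET = 30.0

#: Housekeeping assays on the low-density card.
DEFAULT_HOUSEKEEPING = ("ACTB", "GAPDH", "HPRT1", "PPIA", "RPLP0")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic expression cohort.

    Defaults mirror the validation cohorts of the study the pipeline
    targets: 13 responders vs 7 non-responders (Crohn's disease) measured
    on a 91-gene card, with a strong standardized effect on a minority of
    genes.  ``effect_size`` is the between-group mean shift in units of
    the within-group SD on the log2 scale.
    """

    n_responders: int = 13
    n_nonresponders: int = 7
    n_genes: int = 91
    n_informative: int = 10
    effect_size: float = 2.0
    block_size: int = 1
    block_correlation: float = 0.0
    base_log2_mean: float = 8.0
    gene_level_sd: float = 2.0
    log2_sd: float = 1.0
    disease: str = "CD"
    cohort: str = "validation"
    timepoint: str = "baseline"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ConfigError("each group needs at least one sample")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ConfigError("n_informative must lie in [0, n_genes]")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ConfigError("block_correlation must lie in [0, 1)")
        if self.log2_sd <= 0:
            raise ConfigError("log2_sd must be positive")
        if self.gene_level_sd < 0:
            raise ConfigError("gene_level_sd must be non-negative")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_responders + self.n_nonresponders


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated cohort: expression, annotations, and the ground truth."""

    expression: ExpressionMatrix
    annotations: tuple[SampleAnnotation, ...]
    truth: tuple[str, ...]
    config: SimulationConfig

    def __post_init__(self) -> None:
        genes = set(self.expression.gene_ids)
        if not set(self.truth) <= genes:
            raise ConfigError("truth genes must be a subset of the expression genes")

    @property
    def labels(self) -> list[str]:
        by_id = {a.sample_id: a.label for a in self.annotations}
        return [by_id[s] for s in self.expression.sample_ids]


def _gene_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    # cohort-prefixed so test and validation samples can share one table
    prefix = config.cohort[:1].upper()
    r = [f"{prefix}_R{i + 1:02d}" for i in range(config.n_responders)]
    n = [f"{prefix}_N{i + 1:02d}" for i in range(config.n_nonresponders)]
    return r, n


def simulate_expression_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort from the block-correlated log2-normal model.

    The first ``n_informative`` genes carry the group effect; they are
    grouped into consecutive blocks of ``block_size`` genes sharing an
    exchangeable correlation of ``block_correlation``.  Remaining genes
    are independent noise with identical distributions in both groups.
    """
    rng = substream(config.seed, "expression")
    genes = _gene_ids(config.n_genes)
    resp_ids, nonresp_ids = _sample_ids(config)
    samples = resp_ids + nonresp_ids
    n_samples = len(samples)

    baseline = config.base_log2_mean + config.gene_level_sd * rng.standard_normal(config.n_genes)

    # z: standard normal with exchangeable within-block correlation rho,
    # via the one-factor construction sqrt(rho)*u_block + sqrt(1-rho)*eps.
    rho = config.block_correlation
    eps = rng.standard_normal((config.n_genes, n_samples))
    z = eps.copy()
    if rho > 0 and config.n_informative > 0:
        n_blocks = -(-config.n_informative // config.block_size)
        u = rng.standard_normal((n_blocks, n_samples))
        for b in range(n_blocks):
            lo = b * config.block_size
            hi = min(lo + config.block_size, config.n_informative)
            z[lo:hi] = np.sqrt(rho) * u[b] + np.sqrt(1.0 - rho) * eps[lo:hi]

    log2x = baseline[:, None] + config.log2_sd * z
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(config.n_informative)])
    if config.n_informative:
        shift = signs * config.effect_size * config.log2_sd
        log2x[: config.n_informative, : config.n_responders] += shift[:, None]

    data = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    annotations = tuple(
        SampleAnnotation(
            sample_id=s,
            disease=config.disease,
            cohort=config.cohort,
            timepoint=config.timepoint,
            label=RESPONDER if s in set(resp_ids) else NONRESPONDER,
        )
        for s in samples
    )
    return SimulatedCohort(
        expression=ExpressionMatrix(data),
        annotations=annotations,
        truth=tuple(genes[: config.n_informative]),
        config=config,
    )


def simulate_ct_table(
    cohort: SimulatedCohort,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
    ct_noise_sd: float = 0.25,
    ct_offset: float = DEFAULT_CT_OFFSET,
) -> CtTable:
    """Render the cohort's expression as a qPCR threshold-cycle table.

    Ct = ct_offset - log2(linear expression) + Gaussian measurement noise.
    Housekeeping assays are appended with unit expected expression in
    every sample (group-independent constant expected Ct).  Values are
    clipped into the instrument range (0, 45].
    """
    if ct_noise_sd < 0:
        raise ConfigError("ct_noise_sd must be non-negative")
    overlap = sorted(set(housekeeping) & set(cohort.expression.gene_ids))
    if overlap:
        raise ConfigError(f"housekeeping genes overlap cohort genes: {overlap}")
    rng = substream(cohort.config.seed, "ct_noise")
    expr = cohort.expression.data
    hk = pd.DataFrame(1.0, index=list(housekeeping), columns=expr.columns)
    linear = pd.concat([expr, hk])
    ct = ct_offset - np.log2(linear)
    if ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, ct_noise_sd, size=ct.shape)
    ct = ct.clip(lower=np.nextafter(0.0, 1.0), upper=45.0)
    return CtTable(ct=ct, housekeeping=tuple(housekeeping))


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """Per-group truncated-normal parameters for one clinical covariate."""

    responder_mean: float
    responder_sd: float
    nonresponder_mean: float
    nonresponder_sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.responder_sd < 0 or self.nonresponder_sd < 0:
            raise ConfigError("covariate SDs must be non-negative")
        if self.lower >= self.upper:
            raise ConfigError("lower truncation bound must be below upper")

    def params(self, label: str) -> tuple[float, float]:
        if label == RESPONDER:
            return self.responder_mean, self.responder_sd
        if label == NONRESPONDER:
            return self.nonresponder_mean, self.nonresponder_sd
        raise ConfigError(f"no covariate parameters for label {label!r}")


@dataclass(frozen=True)
class ClinicalConfig:
    """Clinical covariate model for one disease (group means/SDs + bounds)."""

    disease: str
    covariates: Mapping[str, CovariateSpec] = field(default_factory=dict)


def load_clinical_fixture(disease: str) -> ClinicalConfig:
    """Load the packaged covariate fixture ('CD' or 'RA' test cohort)."""
    name = {"CD": "cd_clinical.yaml", "RA": "ra_clinical.yaml"}.get(disease)
    if name is None:
        raise ConfigError(f"no packaged clinical fixture for disease {disease!r}")
    text = resources.files("respanel").joinpath(f"fixtures/{name}").read_text()
    return parse_clinical_config(yaml.safe_load(text))


def parse_clinical_config(doc: Mapping) -> ClinicalConfig:
    covariates = {}
    for name, spec in doc["covariates"].items():
        lower, upper = spec.get("bounds", (-np.inf, np.inf))
        covariates[name] = CovariateSpec(
            responder_mean=float(spec["responder"]["mean"]),
            responder_sd=float(spec["responder"]["sd"]),
            nonresponder_mean=float(spec["nonresponder"]["mean"]),
            nonresponder_sd=float(spec["nonresponder"]["sd"]),
            lower=float(lower),
            upper=float(upper),
        )
    return ClinicalConfig(disease=doc["disease"], covariates=covariates)


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                    lower: float, upper: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lower, upper)))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_clinical_covariates(
    annotations: Sequence[SampleAnnotation],
    clin: ClinicalConfig | Mapping[str, ClinicalConfig],
    seed: int,
) -> list[SampleAnnotation]:
    """Attach truncated-normal baseline covariates to labeled samples.

    ``clin`` is either one ClinicalConfig or a mapping disease -> config;
    each sample draws only its own disease's covariates, with the
    mean/SD of its responder group.  Annotations are otherwise unchanged.
    """
    configs = {clin.disease: clin} if isinstance(clin, ClinicalConfig) else dict(clin)
    missing = sorted({a.disease for a in annotations} - set(configs))
    if missing:
        raise ConfigError(f"no clinical parameters for disease(s): {missing}")
    for a in annotations:
        if a.label is None:
            raise ConfigError(f"sample {a.sample_id!r} is unlabeled")

    rng = substream(seed, "covariates")
    # Draw per (disease, covariate, group) in a fixed order so the stream
    # is reproducible regardless of the caller's sample ordering quirks.
    out: dict[str, dict[str, float]] = {a.sample_id: {} for a in annotations}
    for disease in sorted(configs):
        config = configs[disease]
        for name in config.covariates:
            spec = config.covariates[name]
            for label in (RESPONDER, NONRESPONDER):
                group = [a for a in annotations if a.disease == disease and a.label == label]
                if not group:
                    continue
                mean, sd = spec.params(label)
                values = _draw_truncnorm(rng, mean, sd, spec.lower, spec.upper, len(group))
                for a, v in zip(group, values):
                    out[a.sample_id][name] = float(v)
    return [a.with_covariates({**a.covariates, **out[a.sample_id]}) for a in annotations]


def write_truth_genes(truth: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("gene_id\n" + "".join(f"{g}\n" for g in truth), encoding="utf-8")
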