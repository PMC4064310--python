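"""Domain types, TSV/JSON readers and writers, and clinical labeling rules.

The pipeline moves three kinds of tabular data around: linear-scale
expression matrices (genes x samples), qPCR threshold-cycle (Ct) tables,
and per-sample clinical annotations.  All files are plain TSV (tab
separated, UTF-8, '.' decimal); panel-search results are serialized as a
versioned JSON report.  Readers validate and reject malformed input
rather than coercing it; every writer/reader pair round-trips.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RESPONDER = "responder"
NONRESPONDER = "nonresponder"

DISEASES = ("CD", "RA")
COHORTS = ("test", "validation")
TIMEPOINTS = ("baseline", "week2")
LABELS = (RESPONDER, NONRESPONDER)

#: Ct-file tokens that denote a missing threshold cycle.
MISSING_CT_TOKENS = ("Undetermined", "NA", "")

CT_MAX_CYCLES = 45.0


class FormatError(ValueError):
    """A file violates the expected format (named row/column where possible)."""


class DomainError(ValueError):
    """An operation was called outside its documented domain."""


class ConfigError(ValueError):
    """A configuration object violates its invariants."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Linear-scale gene x sample abundance values.

    ``data`` is a DataFrame indexed by gene id with sample-id columns.
    Values are non-negative; NaN marks a missing relative expression
    (e.g. an undetermined Ct propagated through normalization).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene id(s): {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dupes}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.nanmin(values, initial=0.0) < 0:
            gene, sample = np.argwhere(np.asarray(self.data < 0))[0]
            raise FormatError(
                f"negative value at gene {idx[gene]!r}, sample {cols[sample]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise DomainError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise DomainError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data[list(samples)])

    def drop_incomplete_genes(self) -> "ExpressionMatrix":
        """Drop genes with any missing value (listwise by gene).

        The discriminant stages require complete per-sample vectors, so a
        gene with an undetermined measurement in any sample is excluded.
        """
        return ExpressionMatrix(self.data.dropna(axis=0, how="any"))


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample clinical metadata and the binary response label."""

    sample_id: str
    disease: str
    cohort: str
    timepoint: str
    label: str | None = None
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise FormatError(f"unknown disease {self.disease!r} for sample {self.sample_id!r}")
        if self.cohort not in COHORTS:
            raise FormatError(f"unknown cohort {self.cohort!r} for sample {self.sample_id!r}")
        if self.timepoint not in TIMEPOINTS:
            raise FormatError(f"unknown timepoint {self.timepoint!r} for sample {self.sample_id!r}")
        if self.label is not None and self.label not in LABELS:
            raise FormatError(f"unknown label {self.label!r} for sample {self.sample_id!r}")

    def with_covariates(self, covariates: Mapping[str, float]) -> "SampleAnnotation":
        return replace(self, covariates=dict(covariates))


@dataclass(frozen=True)
class CtTable:
    """Gene x sample qPCR threshold-cycle values with housekeeping genes.

    Ct values lie in (0, 45] cycles or are missing (NaN).  ``housekeeping``
    names the stably expressed reference assays included on the card.
    """

    ct: pd.DataFrame
    housekeeping: tuple[str, ...]

    def __post_init__(self) -> None:
        idx = self.ct.index
        if idx.has_duplicates:
            raise FormatError(f"duplicate gene id(s): {idx[idx.duplicated()].unique().tolist()}")
        if self.ct.columns.has_duplicates:
            raise FormatError("duplicate sample ids in Ct table")
        unknown = [g for g in self.housekeeping if g not in idx]
        if unknown:
            raise FormatError(f"housekeeping genes not in table: {unknown}")
        values = self.ct.to_numpy(dtype=float)
        finite = values[~np.isnan(values)]
        if finite.size and (finite.min() <= 0 or finite.max() > CT_MAX_CYCLES):
            raise FormatError(f"Ct values must lie in (0, {CT_MAX_CYCLES}] cycles or be missing")
        object.__setattr__(self, "housekeeping", tuple(self.housekeeping))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.index if g not in self.housekeeping]


@dataclass(frozen=True)
class PanelResult:
    """A gene panel found by the backward-elimination search.

    ``search_accuracy`` is the accuracy under the search metric on the
    cohort the search ran on; ``loocv_accuracy``, ``loocv_scores`` and
    ``auc`` are filled in by the evaluation stage.  ``trajectory`` logs
    every attempted removal as (gene, accuracy, accepted).
    """

    genes: tuple[str, ...]
    selection_model: str
    search_accuracy: float
    trajectory: tuple[tuple[str, float, bool], ...] = ()
    loocv_accuracy: float | None = None
    loocv_scores: Mapping[str, float] | None = None
    auc: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise DomainError("a panel must contain at least one gene")
        for acc in (self.search_accuracy, self.loocv_accuracy):
            if acc is not None and not 0.0 <= acc <= 100.0:
                raise DomainError(f"accuracy {acc} outside [0, 100]")
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(
            self, "trajectory", tuple((g, float(a), bool(ok)) for g, a, ok in self.trajectory)
        )


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered by how often they appear in high-CV-accuracy panels."""

    entries: tuple[tuple[str, int], ...]
    cv_threshold: float

    def __post_init__(self) -> None:
        counts = [c for _, c in self.entries]
        if any(c1 < c2 for c1, c2 in zip(counts, counts[1:])):
            raise DomainError("ranking counts must be non-increasing")
        object.__setattr__(self, "entries", tuple((g, int(c)) for g, c in self.entries))


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, keep_default_na=False,
            na_values=[], encoding="utf-8",
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{what} file {path.name}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def _to_float(df: pd.DataFrame, what: str, missing_tokens: Sequence[str] = ("NA", "")) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for row, token in df[col].items():
            token = token.strip()
            if token in missing_tokens:
                out.loc[row, col] = math.nan
                continue
            try:
                out.loc[row, col] = float(token)
            except ValueError:
                raise FormatError(
                    f"{what}: non-numeric value {token!r} at row {row!r}, column {col!r}"
                ) from None
    return out


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV: first column gene id, header of sample ids."""
    raw = _read_tsv_matrix(path, "expression")
    return ExpressionMatrix(_to_float(raw, "expression"))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format="%.12g", na_rep="NA",
                       index_label="gene_id", encoding="utf-8")


def read_ct_table(path: str | Path, housekeeping: Sequence[str]) -> CtTable:
    """Read a Ct TSV; tokens 'Undetermined'/'NA'/empty map to missing."""
    raw = _read_tsv_matrix(path, "Ct")
    ct = _to_float(raw, "Ct", missing_tokens=MISSING_CT_TOKENS)
    return CtTable(ct=ct, housekeeping=tuple(housekeeping))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.ct.to_csv(path, sep="\t", float_format="%.12g", na_rep="Undetermined",
                    index_label="gene_id", encoding="utf-8")


_ANNOTATION_COLUMNS = ("sample_id", "disease", "cohort", "timepoint", "label")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample-annotation TSV.

    Required columns: sample_id, disease, cohort, timepoint, label.  An
    empty or 'unlabeled' label token yields label=None.  Any additional
    column is preserved as a named real-valued covariate.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[], encoding="utf-8")
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file missing column(s): {missing}")
    covariate_cols = [c for c in df.columns if c not in _ANNOTATION_COLUMNS]
    out: list[SampleAnnotation] = []
    for _, row in df.iterrows():
        label_token = row["label"].strip()
        label = None if label_token in ("", "unlabeled") else label_token
        covariates = {}
        for col in covariate_cols:
            token = row[col].strip()
            if token in ("", "NA"):
                continue
            try:
                covariates[col] = float(token)
            except ValueError:
                raise FormatError(
                    f"annotation: non-numeric covariate {token!r} in column {col!r} "
                    f"for sample {row['sample_id']!r}"
                ) from None
        out.append(SampleAnnotation(
            sample_id=row["sample_id"], disease=row["disease"], cohort=row["cohort"],
            timepoint=row["timepoint"], label=label, covariates=covariates,
        ))
    ids = [a.sample_id for a in out]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in annotation file")
    return out


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    covariate_cols = sorted({k for a in annotations for k in a.covariates})
    rows = []
    for a in annotations:
        row = {
            "sample_id": a.sample_id, "disease": a.disease, "cohort": a.cohort,
            "timepoint": a.timepoint, "label": a.label if a.label is not None else "unlabeled",
        }
        for col in covariate_cols:
            value = a.covariates.get(col)
            row[col] = "NA" if value is None else f"{value:.12g}"
        rows.append(row)
    pd.DataFrame(rows, columns=list(_ANNOTATION_COLUMNS) + covariate_cols).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Clinical responder labeling
# ---------------------------------------------------------------------------

def classify_cd_response(cdai_baseline: float, cdai_week6: float) -> str:
    """Label a Crohn's disease patient by CDAI change at week 6.

    Responder iff the CDAI decreased by at least 100 points from baseline
    (a decrease of exactly 100 counts as response).
    """
    if cdai_baseline < 0 or cdai_week6 < 0:
        raise DomainError("CDAI scores must be non-negative")
    return RESPONDER if cdai_baseline - cdai_week6 >= 100 else NONRESPONDER


_ACR_RESPONDER = {"ACR0": False, "ACR20": False, "ACR50": True, "ACR70": True}


def classify_ra_response(acr_category: str) -> str:
    """Label a rheumatoid arthritis patient by ACR improvement category.

    ACR50/ACR70 improvement at week 14 counts as response; ACR0/ACR20
    (non- or moderate response) counts as non-response.
    """
    try:
        responder = _ACR_RESPONDER[acr_category]
    except KeyError:
        raise DomainError(f"unknown ACR category {acr_category!r}") from None
    return RESPONDER if responder else NONRESPONDER


# ---------------------------------------------------------------------------
# Panel report (JSON)
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = "1.0"


def _load_report_schema() -> dict:
    text = resources.files("respanel").joinpath("schema/panel_report.schema.json").read_text()
    return json.loads(text)


def validate_panel_report(doc: Mapping) -> None:
    """Check a report document against the shipped schema (required keys/types)."""
    schema = _load_report_schema()
    for key in schema["required"]:
        if key not in doc:
            raise FormatError(f"panel report missing key {key!r}")
    if doc["schema_version"] != REPORT_SCHEMA_VERSION:
        raise FormatError(f"unsupported report schema version {doc['schema_version']!r}")
    panel_required = schema["properties"]["panels"]["items"]["required"]
    for i, panel in enumerate(doc["panels"]):
        for key in panel_required:
            if key not in panel:
                raise FormatError(f"panel {i}: missing key {key!r}")


def _panel_to_record(panel: PanelResult) -> dict:
    return {
        "genes": list(panel.genes),
        "selection_model": panel.selection_model,
        "search_accuracy": panel.search_accuracy,
        "loocv_accuracy": panel.loocv_accuracy,
        "loocv_scores": dict(panel.loocv_scores) if panel.loocv_scores is not None else None,
        "auc": panel.auc,
        "trajectory": [list(step) for step in panel.trajectory],
        "seed": panel.seed,
    }


def _panel_from_record(record: Mapping) -> PanelResult:
    return PanelResult(
        genes=tuple(record["genes"]),
        selection_model=record["selection_model"],
        search_accuracy=record["search_accuracy"],
        trajectory=tuple((g, a, ok) for g, a, ok in record["trajectory"]),
        loocv_accuracy=record["loocv_accuracy"],
        loocv_scores=record["loocv_scores"],
        auc=record["auc"],
        seed=record["seed"],
    )


def write_panel_report(panels: Sequence[PanelResult], ranking: GeneRanking | None,
                       path: str | Path) -> None:
    """Write panels and the membership ranking as a deterministic JSON report."""
    if not panels:
        raise DomainError("panel report requires at least one panel")
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "panels": [_panel_to_record(p) for p in panels],
        "ranking": None if ranking is None else {
            "cv_threshold": ranking.cv_threshold,
            "entries": [[g, c] for g, c in ranking.entries],
        },
    }
    validate_panel_report(doc)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_panel_report(path: str | Path) -> tuple[list[PanelResult], GeneRanking | None]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    validate_panel_report(doc)
    panels = [_panel_from_record(r) for r in doc["panels"]]
    ranking = None
    if doc["ranking"] is not None:
        ranking = GeneRanking(
            entries=tuple((g, c) for g, c in doc["ranking"]["entries"]),
            cv_threshold=doc["ranking"]["cv_threshold"],
        )
    return panels, ranking


def labels_for(matrix: ExpressionMatrix,
               annotations: Iterable[SampleAnnotation]) -> list[str]:
    """Align annotation labels with the matrix's sample order.

    Every sample entering classification must carry a label.
    """
    by_id = {a.sample_id: a for a in annotations}
    labels = []
    for sample in matrix.sample_ids:
        if sample not in by_id:
            raise DomainError(f"sample {sample!r} has no annotation")
        label = by_id[sample].label
        if label is None:
            raise DomainError(f"sample {sample!r} is unlabeled")
        labels.append(label)
    return labels
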