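"""Panel evaluation: LOOCV annotation, ROC/AUC, and membership ranking.

The discriminating power of a panel is summarized two ways: the
leave-one-out cross-validation accuracy, and the ROC curve of the
held-out canonical scores (responders should score higher).  Across the
whole panel pool, genes are ranked by how often they appear in panels
whose cross-validation accuracy clears a threshold - the study's way of
nominating a robust pool of candidate genes for larger cohorts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .cva_lda import DEFAULT_RIDGE, loocv
from .datamodel_io import (
    RESPONDER,
    DomainError,
    ExpressionMatrix,
    GeneRanking,
    PanelResult,
)


@dataclass(frozen=True)
class RocCurve:
    """A ROC curve: (FPR, TPR) points from (0,0) to (1,1), and its area.

    The trapezoid area equals the tie-corrected pair-counting statistic
    P(score_R > score_N) + 1/2 P(score_R = score_N).
    """

    points: tuple[tuple[float, float], ...]
    auc: float

    def __post_init__(self) -> None:
        fprs = [p[0] for p in self.points]
        tprs = [p[1] for p in self.points]
        if self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0):
            raise DomainError("ROC must run from (0,0) to (1,1)")
        if any(a > b for a, b in zip(fprs, fprs[1:])) or any(a > b for a, b in zip(tprs, tprs[1:])):
            raise DomainError("ROC points must be monotone non-decreasing")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> RocCurve:
    """ROC over all distinct score thresholds; larger score = more responder-like."""
    y = np.array([lab == RESPONDER for lab in labels])
    if y.all() or not y.any():
        raise DomainError("ROC needs both classes present")
    s = np.asarray(list(scores), dtype=float)
    fpr, tpr, _ = skmetrics.roc_curve(y, s, drop_intermediate=False)
    points = tuple((float(f), float(t)) for f, t in zip(fpr, tpr))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=points, auc=auc)


def evaluate_panel(
    matrix: ExpressionMatrix,
    labels: Sequence[str],
    panel: PanelResult,
    ridge: float = DEFAULT_RIDGE,
) -> PanelResult:
    """Annotate a panel with LOOCV accuracy, held-out scores, and ROC-AUC.

    The ROC is computed from the held-out canonical scores (not from
    resubstitution scores), so the AUC reflects out-of-sample ranking.
    """
    acc, scores = loocv(matrix, labels, genes=list(panel.genes), ridge=ridge)
    curve = roc_curve(scores.to_numpy(), labels)
    return replace(
        panel,
        loocv_accuracy=acc,
        loocv_scores={s: float(v) for s, v in scores.items()},
        auc=curve.auc,
    )


def rank_genes_by_panel_membership(
    panels: Sequence[PanelResult],
    cv_threshold: float = 80.0,
) -> GeneRanking:
    """Count gene appearances in panels with LOOCV accuracy strictly above the bar.

    Genes appearing in any panel of the pool but in no qualifying panel
    are listed with count 0, so the ranking's universe is the whole pool.
    Sorting is by count descending, gene id ascending on ties.
    """
    for panel in panels:
        if panel.loocv_accuracy is None:
            raise DomainError("panels must be evaluated (LOOCV) before ranking")
    qualifying = [p for p in panels if p.loocv_accuracy > cv_threshold]
    counts: Counter[str] = Counter()
    for panel in qualifying:
        counts.update(panel.genes)
    universe = {g for p in panels for g in p.genes} if qualifying else set()
    entries = sorted(
        ((g, counts.get(g, 0)) for g in universe),
        key=lambda e: (-e[1], e[0]),
    )
    return GeneRanking(entries=tuple(entries), cv_threshold=cv_threshold)


def write_ranking(ranking: GeneRanking, path: str | Path) -> None:
    """Write the membership ranking as a (count, gene) TSV."""
    pd.DataFrame(
        {"count": [c for _, c in ranking.entries],
         "gene_id": [g for g, _ in ranking.entries]}
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_roc_points(curve: RocCurve, path: str | Path) -> None:
    curve.as_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")
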