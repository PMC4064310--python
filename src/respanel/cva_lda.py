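"""Canonical variates / linear discriminant classification of two groups.

For two classes, canonical variates analysis reduces to Fisher's linear
discriminant: the single canonical axis is w = S_W^-1 (mu_R - mu_N), the
direction maximizing the ratio of between-group to within-group scatter.
Samples are classified by which side of a prior-adjusted threshold their
canonical score falls on.

Panels routinely contain more genes than there are patients, which makes
the pooled within-group covariance singular; a small ridge (relative to
the mean diagonal) keeps the axis well defined and deterministic.  The
per-gene F-value (one-way ANOVA between/within variability ratio) feeds
the panel-search selection rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import (
    NONRESPONDER,
    RESPONDER,
    DomainError,
    ExpressionMatrix,
)

#: Ridge added to the pooled within-group covariance, as a fraction of its
#: mean diagonal.  Small enough not to disturb well-conditioned fits,
#: large enough to make singular (genes >= samples) fits deterministic.
DEFAULT_RIDGE = 1e-6


@dataclass(frozen=True)
class GeneFValue:
    """Per-gene one-way ANOVA F: between-group over within-group variability."""

    gene_id: str
    f_value: float


@dataclass(frozen=True)
class CvaModel:
    """A fitted two-class canonical-variates (Fisher LDA) model.

    ``canonical_axis`` holds one weight per gene, oriented so responders
    score higher.  ``threshold`` is the decision cut on the canonical
    score (scores are centered at the training grand centroid, so a
    sample at the centroid scores 0).
    """

    genes: tuple[str, ...]
    group_means: Mapping[str, np.ndarray]
    pooled_within_scatter: np.ndarray
    canonical_axis: np.ndarray
    class_priors: Mapping[str, float]
    threshold: float
    grand_mean: np.ndarray
    ridge: float


def _as_bool_labels(labels: Sequence[str]) -> np.ndarray:
    unknown = sorted(set(labels) - {RESPONDER, NONRESPONDER})
    if unknown:
        raise DomainError(f"unknown label(s): {unknown}")
    return np.array([lab == RESPONDER for lab in labels])


def _design(matrix: ExpressionMatrix, labels: Sequence[str],
            genes: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if len(labels) != matrix.n_samples:
        raise DomainError("labels must align with matrix samples")
    sub = matrix if genes is None else matrix.subset_genes(genes)
    X = sub.data.to_numpy(dtype=float).T  # samples x genes
    if np.isnan(X).any():
        raise DomainError("expression contains missing values; drop incomplete genes first")
    return X, _as_bool_labels(labels), sub.gene_ids


# ---------------------------------------------------------------------------
# Array-level core (used by the panel search, which needs many fast fits)
# ---------------------------------------------------------------------------

def _fit_arrays(X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE):
    """Fit on samples-x-genes X, boolean responder y.

    Returns (axis w, raw-projection threshold, mu_resp, mu_non, S_W).
    Requires both classes present; tolerates a singleton class (its
    within-scatter contribution is zero), which LOOCV folds can produce.
    """
    n, p = X.shape
    n1 = int(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise DomainError("both classes must be present")
    mu1 = X[y].mean(axis=0)
    mu0 = X[~y].mean(axis=0)
    Xc = X - np.where(y, 1.0, 0.0)[:, None] * mu1 - np.where(y, 0.0, 1.0)[:, None] * mu0
    s_w = Xc.T @ Xc / max(n - 2, 1)
    mean_diag = float(s_w.diagonal().mean())
    lam = ridge * (mean_diag if mean_diag > 0 else 1.0)
    d = mu1 - mu0
    reg = s_w + lam * np.eye(p)
    try:
        w = np.linalg.solve(reg, d)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(reg) @ d
    pi1, pi0 = n1 / n, n0 / n
    threshold = 0.5 * float(w @ (mu1 + mu0)) - math.log(pi1 / pi0)
    return w, threshold, mu1, mu0, s_w


def _predict_raw(X: np.ndarray, w: np.ndarray, threshold: float,
                 tie_responder: bool) -> np.ndarray:
    proj = X @ w
    pred = proj > threshold
    ties = proj == threshold
    if ties.any():
        pred[ties] = tie_responder
    return pred


def _accuracy_arrays(X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE) -> float:
    w, threshold, *_ = _fit_arrays(X, y, ridge)
    tie_responder = y.sum() >= (y.size - y.sum())
    pred = _predict_raw(X, w, threshold, tie_responder)
    return 100.0 * float(np.mean(pred == y))


def _loocv_arrays(X: np.ndarray, y: np.ndarray,
                  ridge: float = DEFAULT_RIDGE) -> tuple[float, np.ndarray]:
    n = X.shape[0]
    if n < 3:
        raise DomainError("leave-one-out needs at least 3 samples")
    pred = np.zeros(n, dtype=bool)
    scores = np.zeros(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        X_tr, y_tr = X[keep], y[keep]
        if y_tr.all() or not y_tr.any():
            # Degenerate fold: training contains one class only.
            pred[i] = bool(y_tr[0])
            scores[i] = 0.0
            continue
        w, threshold, *_ = _fit_arrays(X_tr, y_tr, ridge)
        tie_responder = y_tr.sum() >= (y_tr.size - y_tr.sum())
        pred[i] = _predict_raw(X[i:i + 1], w, threshold, tie_responder)[0]
        scores[i] = float(X[i] @ w - X_tr.mean(axis=0) @ w)
    return 100.0 * float(np.mean(pred == y)), scores


def _f_values_arrays(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    n1 = int(y.sum())
    n0 = n - n1
    mu1 = X[y].mean(axis=0)
    mu0 = X[~y].mean(axis=0)
    mu = X.mean(axis=0)
    ssb = n1 * (mu1 - mu) ** 2 + n0 * (mu0 - mu) ** 2
    ssw = ((X[y] - mu1) ** 2).sum(axis=0) + ((X[~y] - mu0) ** 2).sum(axis=0)
    msb = ssb  # one between-group degree of freedom for two classes
    msw = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f[(msw == 0) & (msb == 0)] = 0.0
    f[(msw == 0) & (msb > 0)] = np.inf
    return f


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def f_value(matrix: ExpressionMatrix, labels: Sequence[str], gene_id: str) -> GeneFValue:
    """One-way ANOVA F for a single gene between the two response groups."""
    return f_values(matrix, labels, [gene_id])[0]


def f_values(matrix: ExpressionMatrix, labels: Sequence[str],
             genes: Sequence[str] | None = None) -> list[GeneFValue]:
    """F-values for several genes at once (two groups, each with >= 2 samples)."""
    X, y, gene_ids = _design(matrix, labels, genes)
    if y.sum() < 2 or (~y).sum() < 2:
        raise DomainError("each group needs at least 2 samples for an F-value")
    f = _f_values_arrays(X, y)
    return [GeneFValue(g, float(v)) for g, v in zip(gene_ids, f)]


def fit_cva(matrix: ExpressionMatrix, labels: Sequence[str],
            ridge: float = DEFAULT_RIDGE) -> CvaModel:
    """Fit the two-class canonical-variates model on all genes of ``matrix``.

    The canonical axis is the (ridge-regularized) Fisher direction
    S_W^-1 (mu_R - mu_N); the decision threshold is the midpoint of the
    projected class means shifted by the log prior ratio, with empirical
    class proportions as priors.
    """
    X, y, gene_ids = _design(matrix, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise DomainError("each class needs at least 2 samples")
    w, raw_threshold, mu1, mu0, s_w = _fit_arrays(X, y, ridge)
    grand_mean = X.mean(axis=0)
    return CvaModel(
        genes=tuple(gene_ids),
        group_means={RESPONDER: mu1, NONRESPONDER: mu0},
        pooled_within_scatter=s_w,
        canonical_axis=w,
        class_priors={RESPONDER: float(y.mean()), NONRESPONDER: float(1 - y.mean())},
        threshold=raw_threshold - float(w @ grand_mean),
        grand_mean=grand_mean,
        ridge=ridge,
    )


def canonical_scores(model: CvaModel, matrix: ExpressionMatrix) -> pd.Series:
    """Canonical score of each sample: centered projection on the axis.

    Centering uses the model's training grand centroid, so adding a
    constant vector to every sample at fit time leaves scores unchanged
    and the centroid itself scores 0.  Gene order in ``matrix`` is
    irrelevant; genes are aligned by id.
    """
    sub = matrix.subset_genes(model.genes)
    X = sub.data.to_numpy(dtype=float).T
    return pd.Series((X - model.grand_mean) @ model.canonical_axis,
                     index=sub.sample_ids, name="canonical_score")


def predict(model: CvaModel, matrix: ExpressionMatrix) -> list[str]:
    """Classify samples by the side of the threshold their score falls on.

    A score exactly on the threshold goes to the larger-prior class
    (responder if priors are equal).
    """
    scores = canonical_scores(model, matrix)
    tie_responder = model.class_priors[RESPONDER] >= model.class_priors[NONRESPONDER]
    out = []
    for s in scores:
        if s == model.threshold:
            out.append(RESPONDER if tie_responder else NONRESPONDER)
        else:
            out.append(RESPONDER if s > model.threshold else NONRESPONDER)
    return out


def resubstitution_accuracy(matrix: ExpressionMatrix, labels: Sequence[str],
                            genes: Sequence[str] | None = None,
                            ridge: float = DEFAULT_RIDGE) -> float:
    """Percent of training samples the model classifies correctly."""
    X, y, _ = _design(matrix, labels, genes)
    if y.sum() < 2 or (~y).sum() < 2:
        raise DomainError("each class needs at least 2 samples")
    return _accuracy_arrays(X, y, ridge)


def loocv(matrix: ExpressionMatrix, labels: Sequence[str],
          genes: Sequence[str] | None = None,
          ridge: float = DEFAULT_RIDGE) -> tuple[float, pd.Series]:
    """Leave-one-out cross-validation accuracy and held-out canonical scores.

    Each sample is predicted by a model fitted on the other n-1 samples;
    its held-out score (centered at that fold's training centroid) is
    retained for ROC analysis.  A fold whose training set collapses to a
    single class predicts that remaining majority class.
    """
    X, y, _ = _design(matrix, labels, genes)
    sub_samples = matrix.sample_ids
    acc, scores = _loocv_arrays(X, y, ridge)
    return acc, pd.Series(scores, index=sub_samples, name="loocv_score")
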