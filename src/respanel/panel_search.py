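"""Automated gene-panel generation by backward elimination around the classifier.

Starting from the full gene set, the search repeatedly proposes removing
one gene and keeps the removal whenever classification accuracy does not
drop.  Which gene is proposed is governed by a selection model:

* ``uniform`` - uniformly at random among the not-yet-tested genes;
* ``f_prop``  - at random with probability inversely proportional to the
  gene's F-value (weakly separating genes are tried first, stochastically);
* ``min_f``   - deterministically the gene with the lowest F-value.

A proposed removal that lowers accuracy is rolled back and the gene is
marked tested; a removal that keeps accuracy at least as good is made
permanent, the best-accuracy bar is raised to the new value, and the
tested set is cleared.  The search stops when every remaining gene has
been tested at the current bar.  Per-gene F-values are computed once, on
the full starting matrix.

The stochastic models can escape the deterministic min-F path and find
better-segregating panels; ``search_panels`` therefore restarts them many
times from independent, reproducibly seeded substreams.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from ._rng import substream
from .cva_lda import (
    DEFAULT_RIDGE,
    GeneFValue,
    _accuracy_arrays,
    _design,
    _f_values_arrays,
    _loocv_arrays,
)
from .datamodel_io import DomainError, ExpressionMatrix, PanelResult

SELECTION_MODELS = ("uniform", "f_prop", "min_f")

#: Fixed substream codes per selection model (seeding is independent of
#: the order models are passed in).
_MODEL_CODES = {"uniform": 0, "f_prop": 1, "min_f": 2}

SEARCH_METRICS = ("resubstitution", "loocv")


def _f_prop_weights(f: np.ndarray) -> np.ndarray:
    """Sampling weights proportional to 1/F, with defined edge cases.

    F = +inf genes get weight 0 (they separate perfectly; never propose
    them) unless every gene is infinite, in which case weights are
    uniform.  F = 0 genes get ten times the largest finite 1/F, so they
    are strongly but not exclusively preferred; if no positive finite F
    exists the weights fall back to uniform.
    """
    finite_pos = np.isfinite(f) & (f > 0)
    if not finite_pos.any():
        return np.ones_like(f, dtype=float)
    weights = np.zeros_like(f, dtype=float)
    weights[finite_pos] = 1.0 / f[finite_pos]
    weights[f == 0] = weights[finite_pos].max() * 10.0
    if weights.sum() == 0:
        return np.ones_like(f, dtype=float)
    return weights


def select_gene(
    selectable: Sequence[str],
    f_values: Sequence[GeneFValue] | Mapping[str, float],
    model: str,
    rng: np.random.Generator | None = None,
) -> str:
    """Pick the next elimination candidate according to the selection model."""
    if model not in SELECTION_MODELS:
        raise DomainError(f"unknown selection model {model!r}")
    if not selectable:
        raise DomainError("no selectable genes")
    f_map = (f_values if isinstance(f_values, Mapping)
             else {fv.gene_id: fv.f_value for fv in f_values})
    missing = [g for g in selectable if g not in f_map]
    if missing:
        raise DomainError(f"F-values missing for gene(s): {missing}")
    genes = sorted(selectable)
    f = np.array([f_map[g] for g in genes], dtype=float)
    if model == "min_f":
        return genes[int(np.argmin(f))]  # sorted ids break ties lexicographically
    if rng is None:
        raise DomainError(f"selection model {model!r} requires an rng")
    if model == "uniform":
        return genes[int(rng.integers(len(genes)))]
    weights = _f_prop_weights(f)
    return genes[int(rng.choice(len(genes), p=weights / weights.sum()))]


def backward_eliminate(
    matrix: ExpressionMatrix,
    labels: Sequence[str],
    model: str = "min_f",
    metric: str = "resubstitution",
    rng: np.random.Generator | None = None,
    ridge: float = DEFAULT_RIDGE,
    seed: int | None = None,
) -> PanelResult:
    """Run one backward-elimination pass and return the surviving panel.

    ``metric`` is the accuracy the acceptance rule compares against:
    resubstitution (default; the search first hunts for panels that
    segregate the training cohort) or leave-one-out cross-validation.
    The removal log records every attempt as (gene, accuracy, accepted).
    """
    if metric not in SEARCH_METRICS:
        raise DomainError(f"unknown search metric {metric!r}")
    if matrix.n_genes < 2:
        raise DomainError("backward elimination needs at least 2 genes")
    X, y, gene_ids = _design(matrix, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise DomainError("each class needs at least 2 samples")

    def accuracy(col_idx: list[int]) -> float:
        if metric == "resubstitution":
            return _accuracy_arrays(X[:, col_idx], y, ridge)
        return _loocv_arrays(X[:, col_idx], y, ridge)[0]

    f_all = _f_values_arrays(X, y)  # computed once, before the loop
    f_map = dict(zip(gene_ids, (float(v) for v in f_all)))
    index_of = {g: i for i, g in enumerate(gene_ids)}

    in_model: list[str] = list(gene_ids)
    tested: set[str] = set()
    best = accuracy([index_of[g] for g in in_model])
    log: list[tuple[str, float, bool]] = []

    while True:
        selectable = [g for g in in_model if g not in tested]
        if not selectable or len(in_model) <= 1:
            break
        gene = select_gene(selectable, f_map, model, rng)
        reduced = [g for g in in_model if g != gene]
        acc = accuracy([index_of[g] for g in reduced])
        if acc < best:
            tested.add(gene)  # reinsert: the gene stays, marked tested
            log.append((gene, acc, False))
        else:
            in_model = reduced
            tested.clear()
            best = acc
            log.append((gene, acc, True))

    return PanelResult(
        genes=tuple(in_model),
        selection_model=model,
        search_accuracy=best,
        trajectory=tuple(log),
        seed=seed,
    )


def replay_trajectory(matrix: ExpressionMatrix, panel: PanelResult) -> tuple[str, ...]:
    """Re-apply a panel's logged removal decisions to the full gene set.

    Returns the gene set the log leads to; equality with ``panel.genes``
    is the reproducibility check for a recorded search.
    """
    in_model = list(matrix.gene_ids)
    for gene, _, accepted in panel.trajectory:
        if accepted:
            in_model.remove(gene)
    return tuple(in_model)


def search_panels(
    matrix: ExpressionMatrix,
    labels: Sequence[str],
    models: Sequence[str] = SELECTION_MODELS,
    n_restarts: int = 100,
    metric: str = "resubstitution",
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    annotate_loocv: bool = True,
) -> list[PanelResult]:
    """Build a pool of candidate panels: repeated stochastic restarts + min-F.

    Stochastic models run ``n_restarts`` times, each from a substream
    keyed by (seed, model code, restart index); min-F is deterministic
    and runs once.  Panels with identical gene sets are deduplicated,
    keeping the earliest.  Unless disabled, every panel is annotated with
    its LOOCV accuracy and per-sample held-out scores.
    """
    if n_restarts < 1:
        raise DomainError("n_restarts must be >= 1")
    unknown = sorted(set(models) - set(SELECTION_MODELS))
    if unknown:
        raise DomainError(f"unknown selection model(s): {unknown}")
    results: list[PanelResult] = []
    for model in models:
        if model == "min_f":
            results.append(backward_eliminate(
                matrix, labels, model=model, metric=metric, ridge=ridge, seed=seed))
            continue
        for restart in range(n_restarts):
            rng = substream(seed, "search", _MODEL_CODES[model], restart)
            results.append(backward_eliminate(
                matrix, labels, model=model, metric=metric, rng=rng,
                ridge=ridge, seed=seed))

    seen: set[frozenset[str]] = set()
    unique: list[PanelResult] = []
    for panel in results:
        key = frozenset(panel.genes)
        if key not in seen:
            seen.add(key)
            unique.append(panel)

    if annotate_loocv:
        from .evaluation import evaluate_panel  # local import avoids a cycle
        unique = [evaluate_panel(matrix, labels, p, ridge=ridge) for p in unique]
    return unique
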