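"""Univariate screening of expression data and comparative-Ct normalization.

The screening stage mirrors a standard two-group microarray workflow:
drop the weakest-expressed genes, then flag genes that differ between
responders and non-responders by both a nonparametric test (Mann-Whitney
U) and a linear-scale fold-change cutoff.  The qPCR stage converts raw
threshold cycles to expression relative to a reference (housekeeping)
gene by the comparative-Ct (2^-dCt) method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel_io import (
    RESPONDER,
    CtTable,
    DomainError,
    ExpressionMatrix,
)

#: Largest combined sample size for which the U-test p is exact (enumeration).
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class UnivariateResult:
    """Per-gene screening outcome.

    ``fold_change`` is direction-agnostic (>= 1); ``direction`` is the sign
    of (responder mean - non-responder mean): +1 up in responders, -1
    down, 0 equal.  ``passed`` marks genes clearing both the significance
    and the fold-change cutoffs.
    """

    gene_id: str
    fold_change: float
    direction: int
    p_value: float
    passed: bool
    p_adjusted: float | None = None


def low_intensity_filter(matrix: ExpressionMatrix, fraction: float) -> ExpressionMatrix:
    """Remove the ``fraction`` of genes with the lowest mean raw intensity.

    Genes are ranked by mean intensity across all samples; exactly
    floor(fraction * n_genes) lowest-ranked genes are removed.  Ties at
    the cutoff are broken by (mean, gene_id) lexicographic order, so the
    result is deterministic.
    """
    if not 0.0 <= fraction < 1.0:
        raise DomainError("fraction must lie in [0, 1)")
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise DomainError("cannot filter an empty expression matrix")
    n_remove = math.floor(fraction * matrix.n_genes)
    if n_remove == 0:
        return matrix
    means = matrix.data.mean(axis=1)
    order = sorted(matrix.gene_ids, key=lambda g: (means[g], g))
    keep = [g for g in matrix.gene_ids if g not in set(order[:n_remove])]
    return matrix.subset_genes(keep)


def _group_values(matrix: ExpressionMatrix, labels: Sequence[str],
                  gene_id: str) -> tuple[np.ndarray, np.ndarray]:
    if len(labels) != matrix.n_samples:
        raise DomainError("labels must align with matrix samples")
    row = matrix.data.loc[gene_id].to_numpy(dtype=float)
    mask = np.array([lab == RESPONDER for lab in labels])
    return row[mask], row[~mask]


def fold_change(matrix: ExpressionMatrix, labels: Sequence[str],
                gene_id: str) -> tuple[float, int]:
    """Direction-agnostic linear-scale fold change between group means."""
    resp, nonresp = _group_values(matrix, labels, gene_id)
    if resp.size == 0 or nonresp.size == 0:
        raise DomainError("both groups must be non-empty")
    m_r, m_n = float(resp.mean()), float(nonresp.mean())
    direction = int(np.sign(m_r - m_n))
    lo, hi = min(m_r, m_n), max(m_r, m_n)
    if hi == 0.0:
        return 1.0, 0
    return (math.inf if lo == 0.0 else hi / lo), direction


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Ux counts pairs where x precedes y, with half credit for ties.
    diff = x[:, None] - y[None, :]
    ux = float(np.sum(diff < 0) + 0.5 * np.sum(diff == 0))
    return ux, x.size * y.size - ux


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    count = total = 0
    for idx in combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        ux, uy = _u_statistics(pooled[mask], pooled[~mask])
        total += 1
        if min(ux, uy) <= u_obs + 1e-9:
            count += 1
    return count / total


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U = min(Ux, Uy).

    For combined n <= 12 the p-value is exact, by enumerating every
    assignment of the pooled values to the two groups (valid with ties).
    Larger samples use the normal approximation with tie correction and
    a continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise DomainError("each group needs at least 2 observations")
    ux, uy = _u_statistics(x, y)
    u = min(ux, uy)
    if x.size + y.size <= EXACT_ENUMERATION_MAX_N:
        return u, _exact_two_sided_p(x, y, u)
    return u, _approx_two_sided_p(x, y, u)


def _approx_two_sided_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = x.size, y.size
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, ties = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(ties**3 - ties)) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 1.0
    z = (u - mean_u + 0.5) / math.sqrt(var_u)  # continuity correction toward the mean
    return min(1.0, 2.0 * stats.norm.cdf(z))


def differential_genes(
    matrix: ExpressionMatrix,
    labels: Sequence[str],
    fc_cutoff: float = 1.5,
    alpha: float = 0.05,
    benjamini_hochberg: bool = False,
) -> list[UnivariateResult]:
    """Screen every gene for responder vs non-responder differences.

    A gene passes when p < alpha and fold change >= fc_cutoff.  Results
    for all genes are returned, sorted by p-value then fold change
    (largest first).  Benjamini-Hochberg adjustment is available but off
    by default; when enabled, ``passed`` uses the adjusted p.
    """
    results = []
    for gene in matrix.gene_ids:
        resp, nonresp = _group_values(matrix, labels, gene)
        _, p = mann_whitney_u(resp, nonresp)
        fc, direction = fold_change(matrix, labels, gene)
        results.append((gene, fc, direction, p))
    p_adj = None
    if benjamini_hochberg:
        p_adj = multipletests([r[3] for r in results], method="fdr_bh")[1]
    out = []
    for i, (gene, fc, direction, p) in enumerate(results):
        p_eff = p_adj[i] if p_adj is not None else p
        out.append(UnivariateResult(
            gene_id=gene, fold_change=fc, direction=direction, p_value=p,
            passed=bool(p_eff < alpha and fc >= fc_cutoff),
            p_adjusted=None if p_adj is None else float(p_adj[i]),
        ))
    return sorted(out, key=lambda r: (r.p_value, -r.fold_change, r.gene_id))


def univariate_table(results: Sequence[UnivariateResult]) -> pd.DataFrame:
    """Screening results as a tidy frame (gene, fold_change, direction, p, passed)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "fold_change": [r.fold_change for r in results],
            "direction": [r.direction for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "passed": [r.passed for r in results],
        }
    )


def comparative_ct_normalize(ct: CtTable, reference_gene: str = "PPIA") -> ExpressionMatrix:
    """Relative expression by the comparative-Ct method, 2^-(Ct_g - Ct_ref).

    Each target gene's Ct is referenced to the designated housekeeping
    gene within the same sample.  Housekeeping assays are excluded from
    the output; a sample with a missing reference Ct yields missing
    relative expression for that sample.
    """
    if reference_gene not in ct.housekeeping:
        raise DomainError(
            f"reference gene {reference_gene!r} is not a designated housekeeping gene"
        )
    ref = ct.ct.loc[reference_gene]
    targets = ct.target_genes
    delta = ct.ct.loc[targets].sub(ref, axis=1)
    return ExpressionMatrix(np.exp2(-delta))
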