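"""Expression-level and amplitude pre-filters for rhythm analysis.

Genes with low average expression (mean TPM <= 1) or a small oscillation
range (peak/trough ratio <= 1.3) carry too little signal for rank-based
rhythm detection and are removed before testing.  Both thresholds are
exclusive on the removal side: a gene is kept only if mean TPM and the
max/min ratio strictly exceed their thresholds.  The low-expression rule is
applied first, so a gene failing both rules is tallied once, under it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["FilterReport", "filter_expression"]


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_low_expression_removed: int
    n_low_amplitude_removed: int
    n_retained: int
    min_mean_tpm: float
    min_peak_trough: float

    def to_dict(self) -> dict:
        return asdict(self)


def peak_trough_ratio(tpm: np.ndarray) -> np.ndarray:
    """Per-gene max/min TPM; a zero trough with a positive peak gives +inf."""
    mx = tpm.max(axis=1)
    mn = tpm.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mn > 0, mx / np.where(mn > 0, mn, 1.0), np.inf)
    return np.where(mx == 0, 0.0, ratio)


def filter_expression(
    matrix: ExpressionMatrix,
    min_mean_tpm: float = 1.0,
    min_peak_trough: float = 1.3,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop low-expression and low-amplitude genes.

    A gene is retained iff mean TPM > ``min_mean_tpm`` and max/min ratio
    > ``min_peak_trough`` (both strict).  The filter only looks at the mean,
    max and min of each gene, so the retained set does not depend on the
    order of timepoints, and filtering is idempotent.
    """
    if matrix.n_genes == 0:
        raise ValueError("empty expression matrix")
    tpm = matrix.tpm.to_numpy(dtype=float)
    mean_ok = tpm.mean(axis=1) > min_mean_tpm
    ratio_ok = peak_trough_ratio(tpm) > min_peak_trough

    n_low_expr = int((~mean_ok).sum())
    n_low_amp = int((mean_ok & ~ratio_ok).sum())
    keep = mean_ok & ratio_ok
    out = ExpressionMatrix(
        matrix.tpm.loc[keep].copy(),
        population=matrix.population,
        group=matrix.group,
    ) if keep.any() else _empty_like(matrix, keep)
    report = FilterReport(
        n_input=matrix.n_genes,
        n_low_expression_removed=n_low_expr,
        n_low_amplitude_removed=n_low_amp,
        n_retained=int(keep.sum()),
        min_mean_tpm=min_mean_tpm,
        min_peak_trough=min_peak_trough,
    )
    return out, report


def _empty_like(matrix: ExpressionMatrix, keep) -> ExpressionMatrix:
    em = ExpressionMatrix.__new__(ExpressionMatrix)
    em.tpm = matrix.tpm.loc[keep].copy()
    em.population = matrix.population
    em.group = matrix.group
    return em
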