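"""Between-array normalization methods for two-group expression matrices.

Four classical competitors to the pairwise-difference approach: per-sample
mean centring (global), location-scale by median and IQR, rank-mapping onto
averaged order statistics (quantile), and iterative MA-space local-regression
correction (cyclic loess). All operate on the pooled matrix — both groups
together — and are permutation-equivariant in the samples.
"""

from __future__ import annotations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_model import QUANTILE_METHOD, ExpressionMatrix, ValidationError

__all__ = [
    "normalize_global",
    "normalize_median_iqr",
    "normalize_quantile",
    "normalize_cyclic_loess",
]


def normalize_global(matrix: ExpressionMatrix, recentre: bool = False) -> ExpressionMatrix:
    """Subtract each sample's mean expression (the per-sample mean acts as a
    housekeeping reference shared by all genes).

    With ``recentre`` the grand mean of the input is added back to every entry
    so values stay on the original scale; this does not affect any downstream
    differential statistic.
    """
    values = matrix.values
    out = values - values.mean(axis=0, keepdims=True)
    if recentre:
        out = out + values.mean()
    return matrix.with_values(out)


def normalize_median_iqr(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Location-scale normalization by sample median and IQR.

    Column j maps to ``(y - Med_j) * (IQR_0 / IQR_j) + Med_0`` where Med_0 and
    IQR_0 are the medians of the per-sample medians and IQRs. Every output
    column then shares median Med_0 and IQR IQR_0.
    """
    if matrix.n_samples < 2:
        raise ValidationError("median-IQR normalization needs at least 2 samples")
    values = matrix.values
    med_j = np.median(values, axis=0)
    q75, q25 = np.percentile(values, [75, 25], axis=0, method=QUANTILE_METHOD)
    iqr_j = q75 - q25
    zero = np.flatnonzero(iqr_j == 0)
    if zero.size:
        raise ValidationError(
            f"zero IQR in sample(s) {[matrix.sample_ids[j] for j in zero[:5]]}: "
            "scale normalization is degenerate"
        )
    med_0 = np.median(med_j)
    iqr_0 = np.median(iqr_j)
    out = (values - med_j) * (iqr_0 / iqr_j) + med_0
    return matrix.with_values(out)


def normalize_quantile(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization against the mean order-statistic reference.

    The reference array q has entry r equal to the mean of the r-th order
    statistics over all columns (both groups pooled); each value is replaced
    by the reference entry at its within-column rank, so every output column
    is the same multiset. Ties within a column receive the mean of the
    reference entries over their tied rank range (average-rank convention).
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    values = matrix.values
    m, n = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    ref_cumsum = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(n):
        col_sorted = sorted_vals[:, j]
        # boundaries of runs of tied values in the sorted column
        starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        ends = np.r_[starts[1:], m]
        run_means = (ref_cumsum[ends] - ref_cumsum[starts]) / (ends - starts)
        run_id = np.cumsum(np.r_[True, col_sorted[1:] != col_sorted[:-1]]) - 1
        out[order[:, j], j] = run_means[run_id]
    return matrix.with_values(out)


def _loess_fit(a: np.ndarray, m_vals: np.ndarray, span: float) -> np.ndarray:
    """Fitted M-vs-A trend at the observed A values (local linear, tricube,
    no robustness iterations)."""
    spread = a.max() - a.min()
    fitted = lowess(
        m_vals, a, frac=span, it=0, delta=0.01 * spread, return_sorted=False
    )
    return np.asarray(fitted)


def normalize_cyclic_loess(
    matrix: ExpressionMatrix,
    span: float = 0.7,
    iterations: int = 3,
    mode: str = "fast",
) -> ExpressionMatrix:
    """Cyclic loess normalization in MA space.

    ``pairwise`` mode: for every pair of columns (j, k), regress
    M = y_j - y_k on A = (y_j + y_k) / 2 with a local linear smoother and move
    each column half the fitted offset toward the other; cycle ``iterations``
    times. ``fast`` mode normalizes each column against the current
    column-mean array instead of all pairs — one smoother fit per column per
    iteration, the variant suited to benchmark-scale runs. Deterministic for
    fixed inputs and parameters.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mode not in ("pairwise", "fast"):
        raise ValueError(f"mode must be 'pairwise' or 'fast', got {mode!r}")
    if matrix.n_samples < 2:
        raise ValidationError("cyclic loess needs at least 2 samples")

    values = matrix.values.copy()
    n = values.shape[1]
    for _ in range(iterations):
        if mode == "pairwise":
            for j in range(n - 1):
                for k in range(j + 1, n):
                    a = 0.5 * (values[:, j] + values[:, k])
                    m_vals = values[:, j] - values[:, k]
                    trend = _loess_fit(a, m_vals, span)
                    values[:, j] -= trend / 2
                    values[:, k] += trend / 2
        else:
            mean_array = values.mean(axis=1)
            for j in range(n):
                a = 0.5 * (values[:, j] + mean_array)
                m_vals = values[:, j] - mean_array
                trend = _loess_fit(a, m_vals, span)
                values[:, j] -= trend
    return matrix.with_values(values)
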