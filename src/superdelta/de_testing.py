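"""Classical per-gene two-sample tests, BH adjustment and DEG selection.

These are the inference steps shared by the competitor normalization
pipelines (normalize, then a per-gene t-test, then Benjamini-Hochberg) and
by the oracle benchmark, which runs the pooled t-test directly on the
noise-free matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ExpressionMatrix, GroupDesign

__all__ = [
    "DEResult",
    "two_sample_t",
    "bh_adjust",
    "select_degs",
    "oracle_test",
    "classic_pipeline",
]


@dataclass
class DEResult:
    """Per-gene test output: statistic, df, p_raw, p_adj, log2_fc, is_de."""

    table: pd.DataFrame

    @property
    def is_de(self) -> np.ndarray:
        return self.table["is_de"].to_numpy()


def two_sample_t(
    matrix: ExpressionMatrix, design: GroupDesign, variant: str = "pooled"
) -> pd.DataFrame:
    """Per-gene two-sample t-test (group A minus group B).

    ``pooled`` uses the pooled standard deviation with N - 2 degrees of
    freedom; ``welch`` uses unpooled variances with Satterthwaite degrees of
    freedom. Genes with zero variance in both groups get NA statistics.
    Returns a frame indexed by gene id with columns statistic, df, p_raw,
    log2_fc.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    mask_a, mask_b = design.masks(matrix.sample_ids)
    ya, yb = matrix.values[:, mask_a], matrix.values[:, mask_b]
    n_a, n_b = ya.shape[1], yb.shape[1]
    mean_a, mean_b = ya.mean(axis=1), yb.mean(axis=1)
    ss_a = ((ya - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((yb - mean_b[:, None]) ** 2).sum(axis=1)
    diff = mean_a - mean_b

    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "pooled":
            sp2 = (ss_a + ss_b) / (n_a + n_b - 2)
            statistic = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
            df = np.full(matrix.n_genes, float(n_a + n_b - 2))
            bad = sp2 <= 0
        else:
            va, vb = ss_a / (n_a - 1), ss_b / (n_b - 1)
            v = va / n_a + vb / n_b
            statistic = diff / np.sqrt(v)
            df = v**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
            bad = v <= 0
        statistic[bad] = np.nan
        df[bad] = np.nan
        p_raw = 2.0 * stats.t.sf(np.abs(statistic), df)
    return pd.DataFrame(
        {"statistic": statistic, "df": df, "p_raw": p_raw, "log2_fc": diff},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NAs are excluded from the family size and returned as NA. Adjusted
    values are capped at 1 and monotone in the input ranks:
    p_adj(i) = min_{j >= rank(i)} p_(j) * m / j.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out_ok = np.empty(m)
    out_ok[order] = adj
    out[ok] = out_ok
    return out


def select_degs(
    p_adj: np.ndarray,
    log2_fc: np.ndarray,
    alpha: float = 0.05,
    fc_threshold: float = 1.25,
) -> tuple[np.ndarray, int]:
    """Flag differentially expressed genes by the conjunction rule.

    A gene is called when its BH-adjusted p-value is below ``alpha`` AND its
    absolute log2 fold change exceeds log2(``fc_threshold``). Returns the
    boolean vector and its count; NAs are never called.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    p_adj = np.asarray(p_adj, dtype=float)
    log2_fc = np.asarray(log2_fc, dtype=float)
    with np.errstate(invalid="ignore"):
        flag = (p_adj < alpha) & (np.abs(log2_fc) > np.log2(fc_threshold))
    flag = np.where(np.isnan(p_adj) | np.isnan(log2_fc), False, flag)
    return flag, int(flag.sum())


def oracle_test(noise_free_matrix: ExpressionMatrix, design: GroupDesign) -> pd.DataFrame:
    """Pooled t-test on the per-sample-noise-free matrix.

    The benchmark upper bound: identical to ``two_sample_t(..., "pooled")``
    but named so benchmark tables carry an explicit oracle column. Only
    meaningful on the simulator's alpha-free matrix.
    """
    return two_sample_t(noise_free_matrix, design, variant="pooled")


def classic_pipeline(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    normalizer=None,
    test_variant: str = "welch",
    alpha: float = 0.05,
    fc_threshold: float = 1.25,
    apply_fc_filter: bool = True,
) -> DEResult:
    """Normalize, test per gene, BH-adjust, and flag DEGs.

    ``normalizer`` is any callable ExpressionMatrix -> ExpressionMatrix (or
    None for no normalization). With ``apply_fc_filter`` off, the call rule
    is adjusted-p only.
    """
    norm = normalizer(matrix) if normalizer is not None else matrix
    table = two_sample_t(norm, design, variant=test_variant)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    if apply_fc_filter:
        flag, _ = select_degs(
            table["p_adj"].to_numpy(), table["log2_fc"].to_numpy(), alpha, fc_threshold
        )
    else:
        p = table["p_adj"].to_numpy()
        flag = np.where(np.isnan(p), False, p < alpha)
    table["is_de"] = flag
    return DEResult(table=table)
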