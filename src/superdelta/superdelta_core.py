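"""The super-delta differential expression test.

The method normalizes gene i against every candidate baseline gene i'
separately by forming per-sample differences delta_{ii',j} = y_ij - y_i'j
(the delta step, which cancels sample-specific technical noise exactly),
computes a two-sample t-statistic per pair (the test step), and condenses
each gene's vector of pairwise t-statistics into one representative
statistic (the summary step). The default summarizer is the median fold
trim median (MFTM): fold the row about its median, discard the fraction of
pairwise statistics deviating most from it (the likely pairings with truly
DE baseline genes), take the median of the rest, and multiply by sqrt(2) —
the factor that compensates the doubled variance of a difference of two
i.i.d. errors, so the statistic approximates the t-test one would run on
noise-free data. The baseline gene attaining the trimmed median is the
gene's "pairing gene", its empirically chosen housekeeping reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de_testing import bh_adjust
from .io_model import ExpressionMatrix, GroupDesign, ValidationError

__all__ = [
    "SuperDeltaConfig",
    "SuperDeltaResult",
    "InsufficientBaselineError",
    "select_baseline_genes",
    "pairwise_t_stats",
    "summarize_statistics",
    "superdelta_test",
]

logger = logging.getLogger(__name__)

SQRT2 = np.sqrt(2.0)
ALL = "all"  # sentinel for "use every gene as a baseline candidate"


class InsufficientBaselineError(ValueError):
    """A gene has fewer than 3 defined pairwise statistics to summarize."""


@dataclass
class SuperDeltaConfig:
    """Configuration of a super-delta run.

    summarizer
        ``mftm`` (trimmed median, the recommended default), ``median``
        (untrimmed median) or ``mean`` (untrimmed mean; no pairing gene).
    trim_proportion
        Fraction of pairwise t-statistics with the largest absolute values
        discarded before the median; in [0, 0.5).
    n_baseline
        Number of baseline genes sampled as normalization candidates, or
        ``"all"``. A moderate subset (default 1000) behaves like the full
        set at a fraction of the cost.
    df_rule
        ``pooled`` uses N - 2 degrees of freedom for p-values; ``welch``
        computes each pairwise statistic in Welch form and summarizes the
        Satterthwaite degrees of freedom with the same trimmed median.
    seed
        Drives baseline sampling and pairing-gene tie-breaks.
    """

    summarizer: str = "mftm"
    trim_proportion: float = 0.20
    n_baseline: int | str = 1000
    df_rule: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.summarizer not in ("mftm", "median", "mean"):
            raise ValueError(f"unknown summarizer {self.summarizer!r}")
        if not 0 <= self.trim_proportion < 0.5:
            raise ValueError("trim_proportion must be in [0, 0.5)")
        if self.n_baseline != ALL and int(self.n_baseline) < 10:
            raise ValueError("n_baseline must be >= 10 or 'all'")
        if self.df_rule not in ("pooled", "welch"):
            raise ValueError(f"unknown df_rule {self.df_rule!r}")


@dataclass
class SuperDeltaResult:
    """Per-gene output of :func:`superdelta_test`.

    ``table`` is indexed by gene id with columns ``statistic``,
    ``pairing_gene``, ``effect_log2``, ``p_raw``, ``p_adj``.
    """

    table: pd.DataFrame
    baseline_gene_ids: list[str]
    config: SuperDeltaConfig
    n_undefined_pairs: int = 0
    n_na_genes: int = 0

    @property
    def statistics(self) -> pd.Series:
        return self.table["statistic"]


def select_baseline_genes(
    matrix: ExpressionMatrix, k: int | str, seed: int
) -> list[str]:
    """Draw ``k`` distinct baseline gene ids uniformly without replacement.

    ``"all"`` returns every gene. The returned list preserves the matrix's
    gene order; the draw is reproducible for a fixed seed.
    """
    if k == ALL:
        return list(matrix.gene_ids)
    k = int(k)
    if k > matrix.n_genes:
        raise ValueError(f"k={k} exceeds the {matrix.n_genes} genes available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(matrix.n_genes, size=k, replace=False))
    return [matrix.gene_ids[i] for i in idx]


def _group_sufficient_stats(values: np.ndarray, mask: np.ndarray):
    """Per-row mean, centered rows and sum of squared deviations for one group."""
    block = values[:, mask]
    mean = block.mean(axis=1)
    centered = block - mean[:, None]
    ss = np.einsum("ij,ij->i", centered, centered)
    return mean, centered, ss


def _pairwise_pooled(
    values: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    t_idx: np.ndarray,
    b_idx: np.ndarray,
):
    """Pooled pairwise t matrix via sufficient statistics.

    Row means and centered cross-products give, for every (target, baseline)
    pair, the group means and within-group sums of squares of the difference
    series delta_{ii',j} without materializing it: the matrix of centered
    cross-products supplies the covariance term.
    """
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    n_tot = n_a + n_b
    mean_a, cent_a, ss_a = _group_sufficient_stats(values, mask_a)
    mean_b, cent_b, ss_b = _group_sufficient_stats(values, mask_b)

    cp_a = cent_a[t_idx] @ cent_a[b_idx].T
    cp_b = cent_b[t_idx] @ cent_b[b_idx].T
    ssd_a = np.maximum(ss_a[t_idx][:, None] + ss_a[b_idx][None, :] - 2 * cp_a, 0.0)
    ssd_b = np.maximum(ss_b[t_idx][:, None] + ss_b[b_idx][None, :] - 2 * cp_b, 0.0)

    g = (mean_a - mean_b)  # per-gene group mean difference
    diff = g[t_idx][:, None] - g[b_idx][None, :]
    sp2 = (ssd_a + ssd_b) / (n_tot - 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mat = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    t_mat[sp2 <= 0] = np.nan

    # Welch companions, for the welch df rule
    var_a = ssd_a / (n_a - 1)
    var_b = ssd_b / (n_b - 1)
    v = var_a / n_a + var_b / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t_welch = diff / np.sqrt(v)
        df_welch = v**2 / (
            (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
        )
    t_welch[v <= 0] = np.nan
    df_welch[v <= 0] = np.nan
    return t_mat, t_welch, df_welch, diff


def pairwise_t_stats(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    targets: Sequence[str],
    baselines: Sequence[str],
) -> np.ndarray:
    """Pooled two-sample t-statistics on per-sample gene differences.

    Entry (i, i') is the pooled t computed on delta_{ii',j} = y_ij - y_i'j
    with N - 2 degrees of freedom. Entries where target == baseline, or where
    the pooled variance of the difference is zero, are NaN (undefined), never
    evaluated as 0/0. Because delta subtracts two genes of the same sample,
    the whole matrix is invariant to adding any per-sample constant.
    """
    gene_index = matrix.gene_index()
    try:
        t_idx = np.array([gene_index[g] for g in targets])
        b_idx = np.array([gene_index[g] for g in baselines])
    except KeyError as exc:
        raise ValidationError(f"unknown gene id {exc.args[0]!r}") from None
    mask_a, mask_b = design.masks(matrix.sample_ids)
    t_mat, _, _, _ = _pairwise_pooled(matrix.values, mask_a, mask_b, t_idx, b_idx)
    self_pair = t_idx[:, None] == b_idx[None, :]
    t_mat[self_pair] = np.nan
    n_undef = int(np.isnan(t_mat).sum() - self_pair.sum())
    if n_undef:
        logger.info("pairwise_t_stats: %d zero-variance pairs left undefined", n_undef)
    return t_mat


def _trim_keep_mask(t_mat: np.ndarray, trim_proportion: float):
    """Per-row mask of entries surviving the median fold trim.

    The row's distribution is folded about its median and the
    floor(trim * L) entries with the largest absolute deviation from the
    median are removed (L counts only defined entries). This discards the
    pairs most at odds with the bulk of the row — typically pairings with
    truly DE baseline genes — whichever side of zero they fall on. Ties at
    the boundary keep the earlier index (the stable sort guarantees it).
    """
    defined = ~np.isnan(t_mat)
    l_def = defined.sum(axis=1)
    n_trim = np.floor(trim_proportion * l_def).astype(int)
    row_med = np.full(t_mat.shape[0], np.nan)
    has_any = l_def > 0
    if np.any(has_any):
        row_med[has_any] = np.nanmedian(t_mat[has_any], axis=1)
    deviation = np.abs(t_mat - row_med[:, None])
    order = np.argsort(deviation, axis=1, kind="stable")  # NaN sorted last
    rank = np.empty_like(order)
    rows = np.arange(t_mat.shape[0])[:, None]
    rank[rows, order] = np.arange(t_mat.shape[1])[None, :]
    keep = defined & (rank < (l_def - n_trim)[:, None])
    return keep, l_def


def _median_with_index(values: np.ndarray, keep: np.ndarray, rng: np.random.Generator):
    """Row-wise median of kept entries plus the column index attaining it.

    The median value is the usual midpoint of the two central order
    statistics; for even survivor counts the reported index is drawn
    uniformly between the two central candidates.
    """
    n_rows = values.shape[0]
    masked = np.where(keep, values, np.nan)
    vorder = np.argsort(masked, axis=1, kind="stable")  # NaN last
    l_keep = keep.sum(axis=1)
    ok = l_keep > 0
    lo = np.zeros(n_rows, int)
    hi = np.zeros(n_rows, int)
    lo[ok] = (l_keep[ok] - 1) // 2
    hi[ok] = l_keep[ok] // 2
    rows = np.arange(n_rows)
    idx_lo = vorder[rows, lo]
    idx_hi = vorder[rows, hi]
    med = 0.5 * (masked[rows, idx_lo] + masked[rows, idx_hi])
    med[~ok] = np.nan
    pick_hi = rng.random(n_rows) < 0.5
    pair_idx = np.where(pick_hi, idx_hi, idx_lo)
    return med, np.where(ok, pair_idx, -1)


def summarize_statistics(
    t_row: np.ndarray,
    summarizer: str = "mftm",
    trim_proportion: float = 0.20,
    seed: int = 0,
) -> tuple[float, int | None]:
    """Condense one gene's pairwise t-statistics into its representative value.

    Returns ``(statistic, pairing_index)``; the pairing index refers to the
    position in ``t_row`` whose entry attains the (trimmed) median, and is
    ``None`` for the mean summarizer. Undefined (NaN) entries are ignored;
    fewer than 3 defined entries is an error.
    """
    t_row = np.asarray(t_row, dtype=float)
    defined = ~np.isnan(t_row)
    if defined.sum() < 3:
        raise InsufficientBaselineError(
            f"only {int(defined.sum())} defined pairwise statistics; need >= 3"
        )
    if summarizer == "mean":
        return float(SQRT2 * np.nanmean(t_row)), None
    if summarizer == "median":
        trim_proportion = 0.0
    elif summarizer != "mftm":
        raise ValueError(f"unknown summarizer {summarizer!r}")
    mat = t_row[None, :]
    keep, _ = _trim_keep_mask(mat, trim_proportion)
    med, pair = _median_with_index(mat, keep, np.random.default_rng(seed))
    return float(SQRT2 * med[0]), int(pair[0])


def superdelta_test(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    config: SuperDeltaConfig | None = None,
) -> SuperDeltaResult:
    """Run the full super-delta pipeline on an unnormalized log2 matrix.

    For each gene the baseline set (minus the gene itself) provides a row of
    pairwise t-statistics; the configured summarizer yields the
    representative statistic and pairing gene; two-sided p-values come from
    the t distribution with degrees of freedom per ``config.df_rule``; BH
    adjustment runs over all genes with a defined statistic. The effect
    estimate is the analogous (trimmed) summary of the per-pair group mean
    differences, in log2 units.
    """
    config = config or SuperDeltaConfig()
    baselines = select_baseline_genes(matrix, config.n_baseline, config.seed)
    if config.n_baseline != ALL and int(config.n_baseline) + 1 > matrix.n_genes:
        raise ValueError("need at least n_baseline + 1 genes")

    gene_index = matrix.gene_index()
    t_idx = np.arange(matrix.n_genes)
    b_idx = np.array([gene_index[g] for g in baselines])
    mask_a, mask_b = design.masks(matrix.sample_ids)
    t_pooled, t_welch, df_welch, diff = _pairwise_pooled(
        matrix.values, mask_a, mask_b, t_idx, b_idx
    )
    self_pair = t_idx[:, None] == b_idx[None, :]
    for mat in (t_pooled, t_welch, df_welch, diff):
        mat[self_pair] = np.nan
    n_undefined = int(np.isnan(t_pooled).sum() - self_pair.sum())
    if n_undefined:
        logger.info("superdelta_test: %d zero-variance pairs undefined", n_undefined)

    t_mat = t_pooled if config.df_rule == "pooled" else t_welch
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    m = matrix.n_genes
    n_tot = design.n_total

    if config.summarizer == "mean":
        with np.errstate(invalid="ignore"):
            statistic = SQRT2 * np.nanmean(t_mat, axis=1)
        pairing_idx = np.full(m, -1)
        effect = np.nanmean(diff, axis=1)
        df = (
            np.full(m, float(n_tot - 2))
            if config.df_rule == "pooled"
            else np.nanmean(df_welch, axis=1)
        )
        l_def = (~np.isnan(t_mat)).sum(axis=1)
    else:
        trim = config.trim_proportion if config.summarizer == "mftm" else 0.0
        keep, l_def = _trim_keep_mask(t_mat, trim)
        med, pairing_idx = _median_with_index(t_mat, keep, rng)
        statistic = SQRT2 * med
        # effect: same trim rule applied to the per-pair mean differences
        keep_d, _ = _trim_keep_mask(diff, trim)
        effect, _ = _median_with_index(diff, keep_d, rng)
        if config.df_rule == "pooled":
            df = np.full(m, float(n_tot - 2))
        else:
            df_masked = np.where(keep, df_welch, np.nan)
            df = np.nanmedian(df_masked, axis=1)

    low_info = l_def < 3
    statistic[low_info] = np.nan
    n_na = int(np.isnan(statistic).sum())
    if n_na:
        logger.info("superdelta_test: %d genes with NA statistic excluded from BH", n_na)

    with np.errstate(invalid="ignore"):
        p_raw = 2.0 * stats.t.sf(np.abs(statistic), df)
    p_adj = bh_adjust(p_raw)

    pairing_gene = np.array(
        [baselines[i] if i >= 0 else None for i in pairing_idx], dtype=object
    )
    pairing_gene[np.isnan(statistic)] = None

    table = pd.DataFrame(
        {
            "statistic": statistic,
            "pairing_gene": pairing_gene,
            "effect_log2": effect,
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    return SuperDeltaResult(
        table=table,
        baseline_gene_ids=baselines,
        config=config,
        n_undefined_pairs=n_undefined,
        n_na_genes=n_na,
    )
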