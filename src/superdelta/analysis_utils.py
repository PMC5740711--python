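"""Post-hoc analyses: rank-difference comparison and pairing-gene frequency."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import ValidationError
from .superdelta_core import SuperDeltaResult

__all__ = ["rank_difference", "pairing_frequency", "PairingFrequencyTable"]


def _abs_rank(statistics: pd.Series) -> pd.Series:
    """1-based ranks by descending |statistic|, ties broken by gene id."""
    frame = pd.DataFrame(
        {"abs_stat": statistics.abs(), "gene": statistics.index.astype(str)}
    )
    order = frame.sort_values(
        ["abs_stat", "gene"], ascending=[False, True], kind="stable"
    ).index
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    return ranks.reindex(statistics.index)


def rank_difference(
    result_ref: pd.Series, result_other: pd.Series, top_k: int
) -> pd.DataFrame:
    """Rank shifts of the reference method's top genes in another method.

    Both inputs are per-gene statistics over the same gene universe. Genes
    are ranked by descending absolute statistic (1 = most significant); the
    report covers the reference top ``top_k``, sorted by descending
    rank_difference = rank_other - rank_ref, so genes the other method
    demotes the most come first.
    """
    ref = pd.Series(result_ref, dtype=float)
    other = pd.Series(result_other, dtype=float)
    if set(ref.index) != set(other.index):
        raise ValidationError("the two results cover different gene universes")
    if top_k > len(ref):
        raise ValueError(f"top_k={top_k} exceeds the {len(ref)} genes available")
    rank_ref = _abs_rank(ref)
    rank_other = _abs_rank(other.reindex(ref.index))
    report = pd.DataFrame(
        {
            "rank_ref": rank_ref,
            "rank_other": rank_other,
            "rank_difference": rank_other - rank_ref,
        }
    )
    report = report[report["rank_ref"] <= top_k]
    return report.sort_values(
        ["rank_difference", "rank_ref"], ascending=[False, True], kind="stable"
    )


class PairingFrequencyTable:
    """Counts of how often each baseline gene served as a pairing gene."""

    def __init__(self, counts: pd.Series, min_times: int):
        self.counts = counts  # all genes with count > min_times, descending
        self.min_times = min_times
        # histogram: times-paired -> number of genes, over the reported genes
        self.histogram = counts.value_counts().sort_index(ascending=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PairingFrequencyTable({len(self.counts)} genes paired "
            f"> {self.min_times} times)"
        )


def pairing_frequency(
    result: SuperDeltaResult, min_times: int = 5
) -> PairingFrequencyTable:
    """Tabulate high-frequency pairing genes (counts strictly above
    ``min_times``) — the empirical candidate housekeeping genes.

    Only defined for the mftm and median summarizers; the mean summarizer
    assigns no pairing genes.
    """
    if result.config.summarizer == "mean":
        raise ValidationError("the mean summarizer assigns no pairing genes")
    paired = result.table["pairing_gene"].dropna()
    counts = paired.value_counts()
    kept = counts[counts > min_times].sort_values(ascending=False)
    table = PairingFrequencyTable(kept, min_times)
    table.total_paired_targets = int(len(paired))
    table.all_counts = counts
    return table
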