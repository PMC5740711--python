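"""Data containers, delimited-text I/O and non-specific filtering.

Expression data are log2-scale matrices oriented genes x samples throughout
the package; nothing transposes silently. Missing values are rejected rather
than imputed — the pipeline assumes complete summarized matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GroupDesign",
    "ValidationError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_group_design",
    "iqr_filter",
]

# Quantile convention used everywhere in this package (per-gene IQR filtering
# and median-IQR normalization alike): linear interpolation between order
# statistics, i.e. numpy's default "linear" method.
QUANTILE_METHOD = "linear"


class ValidationError(ValueError):
    """Raised when an input file or container violates a structural contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Parameters
    ----------
    values
        2-D float array, rows correspond to ``gene_ids`` and columns to
        ``sample_ids``.
    gene_ids, sample_ids
        Unique string identifiers; order defines the row/column order.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        m, n = self.values.shape
        if m != len(self.gene_ids):
            raise ValidationError(
                f"row count {m} does not match {len(self.gene_ids)} gene ids"
            )
        if n != len(self.sample_ids):
            raise ValidationError(
                f"column count {n} does not match {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains NaN or infinite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """A copy sharing ids but holding new values of the same shape."""
        return ExpressionMatrix(values, list(self.gene_ids), list(self.sample_ids))

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            self.values[keep],
            [self.gene_ids[i] for i in np.flatnonzero(np.ones(self.n_genes, bool))[keep]]
            if keep.dtype == bool
            else [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


@dataclass
class GroupDesign:
    """Assignment of each sample to one of two groups, labelled ``A`` and ``B``."""

    assignment: Mapping[str, str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)
        if not self.sample_ids:
            self.sample_ids = list(self.assignment)
        bad = {g for g in self.assignment.values() if g not in ("A", "B")}
        if bad:
            raise ValidationError(f"group labels must be 'A' or 'B', got {sorted(bad)}")
        if self.n_a < 2 or self.n_b < 2:
            raise ValidationError(
                f"both groups need at least 2 samples (n_A={self.n_a}, n_B={self.n_b})"
            )

    @property
    def n_a(self) -> int:
        return sum(1 for g in self.assignment.values() if g == "A")

    @property
    def n_b(self) -> int:
        return sum(1 for g in self.assignment.values() if g == "B")

    @property
    def n_total(self) -> int:
        return self.n_a + self.n_b

    def masks(self, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean column masks (group A, group B) aligned to ``sample_ids``."""
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise ValidationError(f"samples missing from design: {missing[:5]}")
        labels = np.array([self.assignment[s] for s in sample_ids])
        return labels == "A", labels == "B"


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples matrix from delimited text.

    The first row holds sample ids, the first column gene ids; the body must
    be numeric. Row and column order are preserved from the file.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValidationError(f"duplicate sample ids in {path}: {dups[:5]}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {path}: {dups[:5]}")
    if frame.columns.has_duplicates:
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in {path}: {dups[:5]}")
    try:
        numeric = frame.astype(float)
    except ValueError:
        # locate the offending cell for the error message
        for gene, row in frame.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric value {cell!r} at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    return ExpressionMatrix.from_frame(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix as delimited text, round-trippable at 10+ significant digits."""
    matrix.to_frame().to_csv(path, sep=delimiter, float_format="%.12g")


def read_group_design(path: str | Path, matrix: ExpressionMatrix,
                      delimiter: str = "\t") -> GroupDesign:
    """Read a two-column (sample_id, group) file covering exactly the matrix samples."""
    frame = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    # tolerate an explicit header row
    if list(frame.iloc[0]) and str(frame.iloc[0, 1]).strip() not in ("A", "B"):
        frame = frame.iloc[1:]
    if frame.shape[1] < 2:
        raise ValidationError("design file needs two columns: sample_id, group")
    assignment = {
        str(s).strip(): str(g).strip() for s, g in zip(frame.iloc[:, 0], frame.iloc[:, 1])
    }
    matrix_samples = set(matrix.sample_ids)
    missing = matrix_samples - set(assignment)
    if missing:
        raise ValidationError(f"design misses samples: {sorted(missing)[:5]}")
    unknown = set(assignment) - matrix_samples
    if unknown:
        raise ValidationError(f"design has unknown samples: {sorted(unknown)[:5]}")
    return GroupDesign(assignment, sample_ids=list(matrix.sample_ids))


def iqr_filter(matrix: ExpressionMatrix, keep_fraction: float) -> ExpressionMatrix:
    """Keep the ``ceil(keep_fraction * m)`` genes with the largest per-gene IQR.

    A non-specific variability filter: low-IQR genes carry little evidence for
    any two-group comparison. Original row order is preserved among survivors;
    ties at the cutoff keep the earlier row.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if matrix.n_samples < 2:
        raise ValidationError("IQR filter needs at least 2 samples")
    q75, q25 = np.percentile(matrix.values, [75, 25], axis=1, method=QUANTILE_METHOD)
    iqr = q75 - q25
    n_keep = int(np.ceil(keep_fraction * matrix.n_genes))
    # stable sort on (-iqr) keeps the earlier row first among ties
    order = np.argsort(-iqr, kind="stable")[:n_keep]
    keep = np.sort(order)  # restore original gene order
    return matrix.subset_genes(keep)
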