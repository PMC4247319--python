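"""Expression-matrix container, log2 transform and quantile normalization.

The analysis operates on a features x samples matrix of log2 intensities.
Before any model fitting, all sample columns are forced onto a common
distribution with quantile normalization: each column's values are replaced
by the cross-sample mean of the order statistics at the corresponding rank,
so that afterwards every column holds exactly the same multiset of values
while within-column ranks are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .io import read_expression_tsv, read_tsv


@dataclass
class ExpressionMatrix:
    """A features x samples log2-intensity matrix with optional class labels.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
    class_labels
        Optional per-sample category with exactly two levels (e.g.
        ``gradeIII`` / ``gradeIV``), indexed by sample id in the same
        order as the matrix columns.
    background_corrected
        Provenance flag only: records whether the upstream summarization
        already applied a background correction. Never alters computation.
    """

    values: pd.DataFrame
    class_labels: pd.Series | None = None
    background_corrected: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = np.argwhere(self.values.isna().to_numpy())[0]
            raise DataError(
                "missing value at feature "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}; "
                "impute or drop before loading"
            )
        if self.values.index.has_duplicates:
            raise DataError("duplicate feature ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample ids in expression matrix")
        if self.class_labels is not None:
            labels = self.class_labels
            if list(labels.index) != list(self.values.columns):
                raise DataError("class labels must be indexed by the matrix sample ids, in order")
            counts = labels.value_counts()
            if len(counts) != 2 or (counts < 2).any():
                raise DataError(
                    "expected exactly two class labels with >= 2 samples each, "
                    f"got {counts.to_dict()}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def classes(self) -> tuple[str, str]:
        """The two class levels in sorted order: (reference, comparison)."""
        if self.class_labels is None:
            raise DataError("matrix carries no class labels")
        return tuple(sorted(self.class_labels.unique()))  # type: ignore[return-value]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.class_labels, self.background_corrected)

    @classmethod
    def from_tsv(cls, expression_path: str | Path,
                 phenotype_path: str | Path | None = None,
                 background_corrected: bool = False) -> "ExpressionMatrix":
        """Load an expression TSV, optionally attaching phenotype class labels."""
        values = read_expression_tsv(expression_path)
        labels = None
        if phenotype_path is not None:
            pheno = read_tsv(phenotype_path)
            labels = pheno.set_index("sample")["class"]
            missing = set(values.columns) - set(labels.index)
            if missing:
                raise DataError(f"phenotype table lacks samples: {sorted(missing)[:5]}")
            labels = labels.loc[list(values.columns)]
        return cls(values, labels, background_corrected)


def log2_transform(matrix: ExpressionMatrix, already_logged: bool = False) -> ExpressionMatrix:
    """Return the matrix on the log2 scale.

    If ``already_logged`` the matrix is returned unchanged; otherwise every
    raw intensity must be strictly positive and is replaced by its log2.
    """
    if already_logged:
        return matrix
    raw = matrix.values.to_numpy()
    if (raw <= 0).any():
        i, j = np.argwhere(raw <= 0)[0]
        raise DataError(
            f"nonpositive intensity {raw[i, j]!r} at feature "
            f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}; "
            "cannot log2-transform"
        )
    return matrix.with_values(pd.DataFrame(
        np.log2(raw), index=matrix.values.index, columns=matrix.values.columns))


def _quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize a features x samples array.

    Each column is replaced by the row means of the column-sorted matrix at
    the corresponding ranks; a within-column tie group receives the mean of
    the reference values at the tied rank positions.
    """
    p, n = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(n):
        col_sorted = x[order[:, j], j]
        assigned = reference.copy()
        # average reference values over each tie group of the sorted column
        start = 0
        for end in range(1, p + 1):
            if end == p or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order[:, j], j] = assigned
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force all sample columns onto the common (row-mean) distribution.

    Post-condition: ``sorted(column_i) == sorted(column_j)`` exactly for all
    pairs of columns, and within-column rank order is preserved.  The
    operation is idempotent and leaves a single-column matrix unchanged.
    """
    out = _quantile_normalize_array(matrix.values.to_numpy(dtype=float))
    return matrix.with_values(pd.DataFrame(
        out, index=matrix.values.index, columns=matrix.values.columns))
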