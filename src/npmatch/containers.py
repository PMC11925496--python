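"""Core data containers: expression matrices and per-sample annotations.

The central currency of the package is a feature-by-sample real matrix with
string identifiers on both axes. Phenotype labels are required by the
correction itself; batch labels, when present, are used only to *evaluate*
how well a correction removed batch structure — never by the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input matrix or annotation violates its contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """A p-feature × n-sample expression matrix.

    Parameters
    ----------
    values
        Real matrix of shape (p, n). Log2-scale intensities unless
        ``is_log`` is False (raw counts).
    feature_ids, sample_ids
        Unique row and column identifiers.
    is_log
        Whether values are on the log2 scale.

    Missing values are rejected at construction: the correction fits
    per-feature linear models and therefore requires a complete matrix.
    Impute upstream if your data contain NAs.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    is_log: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if p != len(self.feature_ids):
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids but {p} rows"
            )
        if n != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {n} columns"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                "matrix contains missing or non-finite values; "
                "missing values are unsupported — impute before correction"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.feature_ids), list(self.sample_ids), self.is_log
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same ids, new values (shape must match)."""
        return ExpressionMatrix(
            np.asarray(values, dtype=float),
            list(self.feature_ids),
            list(self.sample_ids),
            self.is_log,
        )

    def subset_features(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index],
            [self.feature_ids[i] for i in index],
            list(self.sample_ids),
            self.is_log,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, is_log: bool = True) -> "ExpressionMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            is_log,
        )


@dataclass
class SampleAnnotation:
    """Per-sample phenotype label (required) and batch label (optional).

    The phenotype defines the c ≥ 2 condition groups the correction
    stratifies on. The batch label, if present, is reserved for evaluation
    and for known-batch comparator methods.
    """

    sample_ids: list[str]
    phenotype: np.ndarray
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.phenotype = np.asarray([str(x) for x in self.phenotype], dtype=object)
        if self.batch is not None:
            self.batch = np.asarray([str(x) for x in self.batch], dtype=object)
            if len(self.batch) != len(self.sample_ids):
                raise ValidationError("batch length does not match sample ids")
        if len(self.phenotype) != len(self.sample_ids):
            raise ValidationError("phenotype length does not match sample ids")
        _check_unique(self.sample_ids, "sample ids")
        if len(self.classes) < 2:
            raise ValidationError(
                "phenotype must have at least 2 levels; got "
                f"{sorted(set(self.phenotype))}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> list[str]:
        """Phenotype levels in sorted order."""
        return sorted(set(self.phenotype))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_sizes(self) -> dict[str, int]:
        return {c: int(np.sum(self.phenotype == c)) for c in self.classes}

    def aligned_to(self, matrix: ExpressionMatrix) -> "SampleAnnotation":
        """Reorder to the matrix's sample order (matrix order is canonical).

        Raises if the two sample sets differ.
        """
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in matrix.sample_ids if s not in pos]
        if missing:
            raise ValidationError(
                f"samples in matrix but not in annotation: {missing[:5]}"
            )
        extra = [s for s in self.sample_ids if s not in set(matrix.sample_ids)]
        if extra:
            raise ValidationError(
                f"samples in annotation but not in matrix: {extra[:5]}"
            )
        order = [pos[s] for s in matrix.sample_ids]
        return SampleAnnotation(
            list(matrix.sample_ids),
            self.phenotype[order],
            None if self.batch is None else self.batch[order],
        )

    def check_pairing_feasible(self) -> None:
        """Every phenotype level needs ≥ 2 samples for pairing to be defined."""
        for c, size in self.class_sizes().items():
            if size < 2:
                raise ValidationError(
                    f"phenotype level {c!r} has {size} sample(s); "
                    "nearest-pair matching needs at least 2 per level"
                )
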