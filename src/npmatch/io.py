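"""Delimited-text I/O for expression matrices and sample annotations.

Matrices are feature-by-sample: first column holds feature ids, the header
row holds sample ids. Annotations are two- or three-column tables
(sample_id, phenotype[, batch]). Delimiter is inferred from the extension
(``.csv`` → comma, anything else → tab) and can be overridden.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleAnnotation, ValidationError


def _infer_delimiter(path: str | os.PathLike, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(
    path: str | os.PathLike,
    delimiter: str | None = None,
    is_log: bool = True,
) -> ExpressionMatrix:
    """Read a feature-by-sample matrix from delimited text.

    Cells must all be numeric and present; an NA/empty cell raises, since
    downstream correction requires a complete matrix.
    """
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if frame.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric cell in matrix ({exc})") from exc
    if np.isnan(values).any():
        bad = int(np.isnan(values).sum())
        raise ValidationError(
            f"{path}: {bad} missing value(s); missing values are unsupported — "
            "impute before loading"
        )
    feature_ids = [str(i) for i in frame.index]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValidationError(
            f"{path}: duplicate feature ids; run collapse_duplicate_features "
            "on the raw table first"
        )
    return ExpressionMatrix(values, feature_ids, [str(c) for c in frame.columns], is_log)


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    delimiter: str | None = None,
) -> None:
    """Write a matrix as delimited text at full float precision (repr round-trip)."""
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValidationError("refusing to write an empty matrix")
    sep = _infer_delimiter(path, delimiter)
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.17g", index_label="feature")


def read_annotation(
    path: str | os.PathLike,
    delimiter: str | None = None,
) -> SampleAnnotation:
    """Read a sample annotation table: sample_id, phenotype[, batch].

    A header row is expected; column names are free-form (position decides).
    """
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: need at least sample_id and phenotype columns")
    if frame.iloc[:, 0].isna().any() or frame.iloc[:, 1].isna().any():
        raise ValidationError(f"{path}: empty sample id or phenotype cell")
    batch = None
    if frame.shape[1] >= 3:
        batch = frame.iloc[:, 2].to_numpy()
        if pd.isna(batch).any():
            raise ValidationError(f"{path}: empty batch cell")
    return SampleAnnotation(
        list(frame.iloc[:, 0]), frame.iloc[:, 1].to_numpy(), batch
    )


def write_annotation(
    annotation: SampleAnnotation,
    path: str | os.PathLike,
    delimiter: str | None = None,
) -> None:
    sep = _infer_delimiter(path, delimiter)
    data = {"sample_id": annotation.sample_ids, "phenotype": annotation.phenotype}
    if annotation.batch is not None:
        data["batch"] = annotation.batch
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)
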