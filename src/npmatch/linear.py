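"""Linear-model batch removal with a protected covariate design.

Per feature, expression is regressed on [intercept | protected design |
sum-to-zero batch indicators] by ordinary least squares, and only the
fitted batch component is subtracted. Sum-to-zero (deviation) coding makes
the correction remove deviations from the grand mean rather than
re-baselining to an arbitrary reference batch, so the global mean of each
feature is stable. One pseudo-inverse is shared across all features.

This is both the internal engine that removes pairing effects inside the
nearest-pair correction and a standalone known-batch comparator method.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix, SampleAnnotation, ValidationError


def sum_to_zero_design(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Deviation-coded indicator matrix for a categorical factor.

    Levels are sorted; each of the first b−1 levels gets a column that is
    1 for that level, −1 for the last level, 0 otherwise. A constant factor
    yields a matrix with zero columns.
    """
    labels = np.asarray([str(x) for x in labels], dtype=object)
    levels = sorted(set(labels))
    design = np.zeros((labels.size, max(len(levels) - 1, 0)))
    for j, lev in enumerate(levels[:-1]):
        design[labels == lev, j] = 1.0
        design[labels == levels[-1], j] = -1.0
    return design, levels


def treatment_design(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded (drop-first) indicators, no intercept column."""
    labels = np.asarray([str(x) for x in labels], dtype=object)
    levels = sorted(set(labels))
    design = np.zeros((labels.size, max(len(levels) - 1, 0)))
    for j, lev in enumerate(levels[1:]):
        design[labels == lev, j] = 1.0
    return design


def remove_batch_components(
    values: np.ndarray,
    batch: np.ndarray,
    protected: np.ndarray | None = None,
) -> np.ndarray:
    """Return ``values`` minus the fitted batch component, per feature.

    Parameters
    ----------
    values
        (p, n) matrix; features are rows.
    batch
        Length-n categorical labels of the factor to remove.
    protected
        Optional (n, q) design of covariates whose fitted contribution must
        survive the correction (e.g. phenotype indicators). An intercept is
        always included and never needs to be part of ``protected``.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    batch_design, levels = sum_to_zero_design(np.asarray(batch))
    if batch_design.shape[1] == 0:
        return values.copy()
    blocks = [np.ones((n, 1))]
    if protected is not None and protected.size:
        blocks.append(np.asarray(protected, dtype=float))
    blocks.append(batch_design)
    design = np.hstack(blocks)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValidationError(
            f"design is rank-deficient (rank {rank} < {design.shape[1]} columns): "
            f"the batch factor (levels {levels}) is confounded with the "
            "protected covariates"
        )
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    batch_coef = coef[-batch_design.shape[1]:]
    return values - (batch_design @ batch_coef).T


def remove_batch_linear(
    matrix: ExpressionMatrix,
    batch: np.ndarray | None = None,
    annotation: SampleAnnotation | None = None,
    protect_phenotype: bool = True,
) -> ExpressionMatrix:
    """Known-batch comparator: regress out a recorded batch factor.

    ``batch`` defaults to ``annotation.batch``. When ``protect_phenotype``
    is set (default) the phenotype design is included in the fit so that
    biological differences are not absorbed into the batch term.
    """
    if batch is None:
        if annotation is None or annotation.batch is None:
            raise ValidationError("no batch labels supplied")
        batch = annotation.batch
    batch = np.asarray(batch)
    if batch.size != matrix.n_samples:
        raise ValidationError("batch labels do not match sample count")
    protected = None
    if protect_phenotype and annotation is not None:
        aligned = annotation.aligned_to(matrix)
        protected = treatment_design(aligned.phenotype)
    corrected = remove_batch_components(matrix.values, batch, protected)
    return matrix.with_values(corrected)


def mean_center_batches(
    matrix: ExpressionMatrix, batch: np.ndarray
) -> ExpressionMatrix:
    """Naive known-batch comparator: per feature, shift each batch's mean to
    the grand mean. Equivalent to batch removal with no protected design."""
    return matrix.with_values(remove_batch_components(matrix.values, batch, None))
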