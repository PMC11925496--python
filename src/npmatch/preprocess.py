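"""Preprocessing chain from raw counts to the normalized log matrix.

The standard chain is: collapse duplicated feature ids (per-sample mean),
drop features undetected in every sample, within-sample CPM + log2(x+1),
then across-sample quantile normalization. Each step is exposed on its own
so users with already-normalized matrices can skip it entirely.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix, ValidationError


def collapse_duplicate_features(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average rows sharing a feature id, keeping first-occurrence order.

    Constructs the result without going through ExpressionMatrix validation
    of the input's duplicate ids (the input is allowed to carry duplicates
    only at this stage, so it arrives as raw arrays via ``from_raw``)."""
    ids = matrix.feature_ids
    if len(set(ids)) == len(ids):
        return matrix.copy()
    return _collapse(matrix.values, ids, matrix.sample_ids, matrix.is_log)


def collapse_from_raw(
    values: np.ndarray,
    feature_ids: list[str],
    sample_ids: list[str],
    is_log: bool = False,
) -> ExpressionMatrix:
    """Collapse duplicates in a raw table that cannot yet be a valid matrix."""
    return _collapse(np.asarray(values, dtype=float), feature_ids, sample_ids, is_log)


def _collapse(values, feature_ids, sample_ids, is_log) -> ExpressionMatrix:
    first_seen: dict[str, int] = {}
    groups: dict[str, list[int]] = {}
    for i, f in enumerate(feature_ids):
        if f not in first_seen:
            first_seen[f] = i
        groups.setdefault(f, []).append(i)
    order = sorted(first_seen, key=first_seen.get)
    out = np.vstack([values[groups[f]].mean(axis=0) for f in order])
    return ExpressionMatrix(out, order, list(sample_ids), is_log)


def drop_undetected(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove features that are zero in every sample (raw counts)."""
    keep = np.flatnonzero((matrix.values != 0).any(axis=1))
    if keep.size == 0:
        raise ValidationError("all features are undetected across all samples")
    if keep.size == matrix.n_features:
        return matrix.copy()
    return matrix.subset_features(keep)


def cpm_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million within each sample, then log2(CPM + 1)."""
    counts = matrix.values
    if (counts < 0).any():
        raise ValidationError("negative counts encountered")
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        names = [matrix.sample_ids[i] for i in zero[:5]]
        raise ValidationError(f"zero library size for sample(s): {names}")
    out = np.log2(counts / libsize * 1e6 + 1.0)
    result = matrix.with_values(out)
    result.is_log = True
    return result


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force all samples to share the mean empirical distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    order statistics; tied values within a sample receive the mean of the
    reference values over their tied positions.
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    x = matrix.values
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # average the reference over tie groups
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=mapped)
        out[:, j] = (sums / counts)[inverse]
    return matrix.with_values(out)


def preprocess_counts(
    matrix: ExpressionMatrix,
    quantile: bool = True,
    keep_undetected: bool = False,
) -> ExpressionMatrix:
    """Full chain: collapse duplicates → drop undetected → CPM/log2 → quantile."""
    out = collapse_duplicate_features(matrix)
    if not keep_undetected:
        out = drop_undetected(out)
    out = cpm_log2(out)
    if quantile:
        out = quantile_normalize(out)
    return out
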