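"""Batch-correction quality metrics and the integrated score.

Four per-dataset metrics quantify how well a correction restored the
phenotype signal: the number of differentially expressed genes between
phenotype classes, the average silhouette width of the phenotype
clustering, the signal-to-noise ratio of log2 fold changes, and the PC1
ratio (how much the leading singular component dominates the
phenotype-correlated variance). Three of them (DEGs, silhouette, SNR) are
combined into one integrated score: the geometric mean of their
corrected/uncorrected ratios, which is exactly 1 for the uncorrected
reference by construction. Across datasets, methods are compared by the
mean rank of their scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score as _sklearn_silhouette

from .containers import ExpressionMatrix, SampleAnnotation, ValidationError
from . import dge as _dge

SS_FLOOR = 1e-3  # ln of a nonpositive silhouette is undefined; floor loudly


def silhouette(matrix: ExpressionMatrix, labels: np.ndarray) -> float:
    """Mean silhouette width (b − a)/max(a, b) over samples, Euclidean
    distance over the feature space. Singleton clusters contribute 0."""
    labels = np.asarray([str(x) for x in labels], dtype=object)
    if labels.size != matrix.n_samples:
        raise ValidationError("labels do not match sample count")
    if len(set(labels)) < 2:
        raise ValidationError("silhouette needs at least 2 label levels")
    value = float(_sklearn_silhouette(matrix.values.T, labels, metric="euclidean"))
    assert -1.0 <= value <= 1.0
    return value


def snr(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    dge_results: pd.DataFrame | None = None,
    contrast: tuple[str, str] | None = None,
) -> float:
    """Signal-to-noise ratio: mean |log2FC| over features divided by the
    mean per-feature standard deviation across all samples."""
    if dge_results is None:
        dge_results = _dge.moderated_t_test(matrix, annotation, contrast)
    signal = float(np.abs(dge_results["log2fc"].to_numpy()).mean())
    noise = float(matrix.values.std(axis=1, ddof=1).mean())
    if noise == 0:
        raise ValidationError("constant matrix: average SD is zero")
    value = signal / noise
    assert value >= 0.0
    return value


def _encodings(phenotype: np.ndarray) -> list[np.ndarray]:
    classes = sorted(set(phenotype))
    if len(classes) == 2:
        return [(phenotype == classes[1]).astype(float)]
    return [(phenotype == c).astype(float) for c in classes]


def pc1_ratio(matrix: ExpressionMatrix, annotation: SampleAnnotation) -> float:
    """ρ₁ / Σ_j ρ_j, with ρ_j = |cor(component-j sample scores, phenotype)|.

    The SVD is taken on the feature-centered matrix; only components with
    nonzero singular value enter. Two-level phenotypes are encoded 0/1;
    for more levels ρ_j is the maximum over one-vs-rest encodings.
    """
    aligned = annotation.aligned_to(matrix)
    if matrix.n_samples < 3:
        raise ValidationError("PC1 ratio needs at least 3 samples")
    x = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    keep = svals > svals[0] * 1e-12 if svals[0] > 0 else np.zeros_like(svals, bool)
    if not keep.any():
        raise ValidationError("degenerate SVD: matrix has no variation")
    vt = vt[keep]
    encodings = _encodings(aligned.phenotype)
    rho = np.empty(vt.shape[0])
    for j in range(vt.shape[0]):
        scores = vt[j]
        if scores.std() == 0:
            rho[j] = 0.0
            continue
        rho[j] = max(
            abs(stats.pearsonr(scores, enc)[0]) if enc.std() > 0 else 0.0
            for enc in encodings
        )
    total = rho.sum()
    if total == 0:
        raise ValidationError("phenotype uncorrelated with every component")
    value = float(rho[0] / total)
    assert 0.0 <= value <= 1.0
    return value


@dataclass
class MetricsReport:
    """Per-method metric values on one dataset."""

    method_name: str
    n_degs: int
    silhouette: float
    snr: float
    pc1_ratio: float
    batch_silhouette: float | None = None
    score: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    method_name: str = "none",
    contrast: tuple[str, str] | None = None,
    lfc_cut: float = _dge.DEFAULT_LFC_CUT,
    fdr_cut: float = _dge.DEFAULT_FDR_CUT,
) -> MetricsReport:
    """Compute every per-dataset metric on one (possibly corrected) matrix.

    Batch silhouette is included when the annotation carries batch labels
    with ≥ 2 levels (lower after correction = better batch mixing).
    """
    aligned = annotation.aligned_to(matrix)
    results = _dge.moderated_t_test(matrix, aligned, contrast)
    batch_ss = None
    if aligned.batch is not None and len(set(aligned.batch)) >= 2:
        batch_ss = silhouette(matrix, aligned.batch)
    return MetricsReport(
        method_name=method_name,
        n_degs=_dge.count_degs(results, lfc_cut, fdr_cut),
        silhouette=silhouette(matrix, aligned.phenotype),
        snr=snr(matrix, aligned, results),
        pc1_ratio=pc1_ratio(matrix, aligned),
        batch_silhouette=batch_ss,
    )


def _floored_ratio(current: float, reference: float, what: str) -> float:
    floor = 1.0 if what == "n_degs" else SS_FLOOR
    cur, ref = float(current), float(reference)
    if cur <= 0 or ref <= 0:
        warnings.warn(
            f"nonpositive {what} ({cur} / {ref}); flooring at {floor} before "
            "the log-ratio — interpret the integrated score with caution",
            stacklevel=3,
        )
        cur, ref = max(cur, floor), max(ref, floor)
    return cur / ref


def integrated_score(current: MetricsReport, reference: MetricsReport) -> float:
    """Geometric mean of the DEG, silhouette, and SNR ratios vs. the
    uncorrected reference: Score = exp([ln r_DEG + ln r_SS + ln r_SNR]/3).

    Ratios are formed before taking logs, so evaluating the reference
    against itself gives exactly 1.
    """
    ratios = [
        _floored_ratio(current.n_degs, reference.n_degs, "n_degs"),
        _floored_ratio(current.silhouette, reference.silhouette, "silhouette"),
        _floored_ratio(current.snr, reference.snr, "snr"),
    ]
    return float(np.exp(np.mean(np.log(ratios))))


def mean_rank(scores: pd.DataFrame) -> pd.Series:
    """Mean per-dataset rank of each method (rank 1 = highest score).

    ``scores`` is a methods × datasets grid with no missing cells; ties get
    the average rank.
    """
    if scores.isna().any().any():
        raise ValidationError("score grid has missing cells")
    ranks = scores.apply(
        lambda col: pd.Series(
            stats.rankdata(-col.to_numpy(), method="average"), index=col.index
        ),
        axis=0,
    )
    return ranks.mean(axis=1).sort_values()


def permutation_control(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    config=None,
    seed: int = 0,
) -> MetricsReport:
    """Negative control: correct under permuted phenotype labels, then
    evaluate against the TRUE labels.

    A correction that only works by exploiting genuine phenotype structure
    should lose its advantage here.
    """
    from .core import npm_correct, NpmConfig

    config = config or NpmConfig()
    aligned = annotation.aligned_to(matrix)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(aligned.n_samples)
    shuffled = SampleAnnotation(
        list(aligned.sample_ids), aligned.phenotype[perm], aligned.batch
    )
    corrected = npm_correct(matrix, shuffled, config)
    return evaluate(corrected, aligned, method_name=f"npm-permuted-seed{seed}")
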