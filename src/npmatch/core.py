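"""Nearest-pair matching correction of latent batch effects.

The method corrects batch structure in a normalized log expression matrix
using only phenotype labels — no batch vector. The stages are:

1. keep the top most-variable features (default 2000);
2. 0-center each feature globally, then within each phenotype group, so
   class mean differences do not bias inter-sample similarity;
3. compute inter-sample distances (1 − Pearson r by default, range [0, 2],
   so anti-correlated samples are maximally distant; or Euclidean);
4. for every sample ("anchor") find its k nearest samples in *each*
   phenotype group, self excluded — n·k·c pairs in total;
5. expand to a fully paired matrix over all features: one column per pair
   carrying the neighbor's profile, labelled with the anchor's identity
   (the pseudo-batch) and the neighbor's phenotype, plus the anchor's own
   column per anchor block by default;
6. regress out the between-anchor-block "pairing effects" with a linear
   model that protects the phenotype design;
7. condense back to the original p × n shape by averaging, per feature,
   every corrected copy of each original sample.

Within a pair, batch differences are small by construction (neighbors are
the most similar profiles available), while systematic offsets *between*
pairs capture batch-related variation without explicit batch labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, SampleAnnotation, ValidationError
from .linear import remove_batch_components, treatment_design

DISTANCE_METHODS = ("pearson", "euclidean")
DISTANCE_TRANSFORMS = ("signed", "abs")


@dataclass
class NpmConfig:
    """Tuning knobs of the nearest-pair correction.

    n_top_features
        Number of most-variable features used for distance computation
        (clamped to p with a warning). The correction itself always runs
        on all features.
    k
        Neighbors per phenotype class per anchor; must satisfy
        k ≤ smallest class size − 1 (self is excluded within the own class).
    distance
        "pearson" (1 − r transform) or "euclidean".
    distance_transform
        "signed" → d = 1 − r (anti-correlation maximally distant, default);
        "abs" → d = 1 − |r| (sensitivity-analysis alternative).
    include_self_columns
        Whether each anchor's own column joins its block in the paired
        matrix (default True: guarantees every sample has at least one
        corrected copy to condense).
    """

    n_top_features: int = 2000
    k: int = 1
    distance: str = "pearson"
    distance_transform: str = "signed"
    include_self_columns: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_top_features < 1:
            raise ValidationError("n_top_features must be positive")
        if self.k < 1:
            raise ValidationError("k must be positive")
        if self.distance not in DISTANCE_METHODS:
            raise ValidationError(f"distance must be one of {DISTANCE_METHODS}")
        if self.distance_transform not in DISTANCE_TRANSFORMS:
            raise ValidationError(
                f"distance_transform must be one of {DISTANCE_TRANSFORMS}"
            )

    def validate_against(self, annotation: SampleAnnotation) -> None:
        annotation.check_pairing_feasible()
        smallest = min(annotation.class_sizes().values())
        if self.k > smallest - 1:
            raise ValidationError(
                f"k={self.k} infeasible: smallest phenotype class has {smallest} "
                f"samples, so k can be at most {smallest - 1} "
                "(self is excluded within the own class)"
            )


@dataclass
class PairTable:
    """Nearest neighbors of every anchor in every phenotype class.

    ``neighbors[anchor_id][class_label]`` is the ordered list of the k
    nearest sample ids of that class (self excluded), with matching
    nondecreasing distances in ``distances``. The flattened pair vector
    has length L = n · k · c.
    """

    anchor_ids: list[str]
    class_labels: list[str]
    k: int
    neighbors: dict[str, dict[str, list[str]]]
    distances: dict[str, dict[str, list[float]]]

    def __len__(self) -> int:
        return len(self.anchor_ids) * self.k * len(self.class_labels)

    def flatten(self) -> list[tuple[str, str, str, float]]:
        """All (anchor, class, neighbor, distance) tuples, length n·k·c."""
        out = []
        for a in self.anchor_ids:
            for c in self.class_labels:
                for nb, d in zip(self.neighbors[a][c], self.distances[a][c]):
                    out.append((a, c, nb, d))
        return out


@dataclass
class PairedMatrix:
    """Expanded p × L matrix: one column per (anchor, neighbor) pair."""

    values: np.ndarray
    feature_ids: list[str]
    column_anchor: np.ndarray
    column_source: np.ndarray
    column_phenotype: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def select_top_variable(matrix: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the ``n_top`` features with the largest sample variance.

    Row order among the selected features is preserved; ties break by
    first occurrence.
    """
    p = matrix.n_features
    if n_top >= p:
        if n_top > p:
            warnings.warn(
                f"n_top_features={n_top} exceeds p={p}; using all features",
                stacklevel=2,
            )
        return matrix.copy()
    variances = matrix.values.var(axis=1, ddof=1)
    # stable sort on negated variance keeps first-occurrence order for ties
    ranked = np.argsort(-variances, kind="stable")[:n_top]
    return matrix.subset_features(np.sort(ranked))


def center_features(
    matrix: ExpressionMatrix, annotation: SampleAnnotation
) -> ExpressionMatrix:
    """0-center each feature globally, then within each phenotype group."""
    aligned = annotation.aligned_to(matrix)
    x = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    for cls in aligned.classes:
        mask = aligned.phenotype == cls
        if mask.sum() == 1:
            warnings.warn(
                f"phenotype level {cls!r} has a single sample; its centered "
                "profile is identically zero",
                stacklevel=2,
            )
        x[:, mask] -= x[:, mask].mean(axis=1, keepdims=True)
    return matrix.with_values(x)


def sample_distances(
    matrix: ExpressionMatrix,
    method: str = "pearson",
    transform: str = "signed",
) -> np.ndarray:
    """Symmetric n × n inter-sample distance matrix with zero diagonal.

    For ``pearson`` the correlation r between sample profiles is mapped to
    a one-dimensional distance: d = 1 − r (default; r = 1 → 0, r = −1 → 2)
    or d = 1 − |r| with ``transform="abs"``.
    """
    x = matrix.values
    n = x.shape[1]
    if n < 2:
        raise ValidationError("need at least 2 samples for distances")
    if method == "pearson":
        sd = x.std(axis=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = [matrix.sample_ids[i] for i in flat[:5]]
            raise ValidationError(
                f"zero-variance sample(s) under pearson distance: {names}"
            )
        r = np.corrcoef(x.T)
        d = 1.0 - (np.abs(r) if transform == "abs" else r)
    elif method == "euclidean":
        sq = (x**2).sum(axis=0)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (x.T @ x)
        d = np.sqrt(np.maximum(d2, 0.0))
    else:
        raise ValidationError(f"unknown distance method {method!r}")
    np.fill_diagonal(d, 0.0)
    return np.maximum((d + d.T) / 2.0, 0.0)


def find_pairs(
    distances: np.ndarray,
    annotation: SampleAnnotation,
    k: int,
    sample_ids: list[str] | None = None,
) -> PairTable:
    """k nearest samples of every phenotype class, per anchor, self excluded.

    The single global distance matrix is partitioned by class. Ties break
    by ascending sample index, making the search fully deterministic.
    """
    sample_ids = list(sample_ids or annotation.sample_ids)
    n = len(sample_ids)
    if distances.shape != (n, n):
        raise ValidationError("distance matrix does not match sample count")
    lookup = dict(zip(annotation.sample_ids, annotation.phenotype))
    try:
        phen = np.asarray([lookup[s] for s in sample_ids], dtype=object)
    except KeyError as exc:
        raise ValidationError(f"sample {exc} missing from annotation") from exc
    classes = annotation.classes
    class_index = {c: np.flatnonzero(phen == c) for c in classes}
    for c, idx in class_index.items():
        available = idx.size  # self removed later where applicable
        if available - 1 < k:
            raise ValidationError(
                f"k={k} infeasible for class {c!r}: only {available} samples "
                f"(need at least {k + 1} so self can be excluded)"
            )
    neighbors: dict[str, dict[str, list[str]]] = {}
    dists: dict[str, dict[str, list[float]]] = {}
    for i, anchor in enumerate(sample_ids):
        neighbors[anchor] = {}
        dists[anchor] = {}
        for c in classes:
            cand = class_index[c][class_index[c] != i]
            d = distances[i, cand]
            order = np.lexsort((cand, d))[:k]
            chosen = cand[order]
            neighbors[anchor][c] = [sample_ids[j] for j in chosen]
            dists[anchor][c] = [float(distances[i, j]) for j in chosen]
    return PairTable(sample_ids, classes, k, neighbors, dists)


def build_paired_matrix(
    matrix: ExpressionMatrix,
    pairs: PairTable,
    annotation: SampleAnnotation,
    include_self_columns: bool = True,
) -> PairedMatrix:
    """Expand the full-feature matrix into one column per pair.

    Each column is a verbatim copy of the neighbor's profile, labelled with
    the anchor id (the pseudo-batch the pairing-effect removal blocks on)
    and the neighbor's phenotype. With ``include_self_columns`` each anchor
    block additionally contains the anchor's own column.
    """
    aligned = annotation.aligned_to(matrix)
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    phen = {s: aligned.phenotype[i] for i, s in enumerate(matrix.sample_ids)}
    if set(pairs.anchor_ids) != set(matrix.sample_ids):
        raise ValidationError("pair table and matrix cover different samples")
    cols: list[int] = []
    anchors: list[str] = []
    sources: list[str] = []
    for a in pairs.anchor_ids:
        if include_self_columns:
            cols.append(pos[a])
            anchors.append(a)
            sources.append(a)
        for c in pairs.class_labels:
            for nb in pairs.neighbors[a][c]:
                cols.append(pos[nb])
                anchors.append(a)
                sources.append(nb)
    return PairedMatrix(
        matrix.values[:, cols].copy(),
        list(matrix.feature_ids),
        np.asarray(anchors, dtype=object),
        np.asarray(sources, dtype=object),
        np.asarray([phen[s] for s in sources], dtype=object),
    )


def remove_pairing_effects(paired: PairedMatrix) -> PairedMatrix:
    """Regress out between-anchor-block offsets, protecting phenotype.

    Per feature, expression over the L paired columns is fit on
    [intercept | phenotype indicators | sum-to-zero anchor-block
    indicators]; only the anchor-block component is subtracted.
    """
    protected = treatment_design(paired.column_phenotype)
    corrected = remove_batch_components(
        paired.values, paired.column_anchor, protected
    )
    return PairedMatrix(
        corrected,
        list(paired.feature_ids),
        paired.column_anchor.copy(),
        paired.column_source.copy(),
        paired.column_phenotype.copy(),
    )


def condense(
    paired: PairedMatrix, original_sample_ids: list[str]
) -> ExpressionMatrix:
    """Average every corrected copy of each original sample, restoring p × n."""
    blocks = []
    for s in original_sample_ids:
        mask = paired.column_source == s
        count = int(mask.sum())
        if count == 0:
            raise ValidationError(
                f"sample {s!r} never occurs in the paired matrix; it was "
                "nobody's nearest neighbor — rerun with include_self_columns=True"
            )
        blocks.append(paired.values[:, mask].mean(axis=1))
    return ExpressionMatrix(
        np.column_stack(blocks), list(paired.feature_ids), list(original_sample_ids)
    )


def npm_correct(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    config: NpmConfig | None = None,
) -> ExpressionMatrix:
    """Run the full nearest-pair matching correction.

    Returns a corrected matrix with exactly the input's shape and ids.
    Deterministic: identical inputs and config give bitwise-identical
    output.
    """
    config = config or NpmConfig()
    aligned = annotation.aligned_to(matrix)
    config.validate_against(aligned)
    top = select_top_variable(matrix, config.n_top_features)
    centered = center_features(top, aligned)
    d = sample_distances(centered, config.distance, config.distance_transform)
    pairs = find_pairs(d, aligned, config.k, matrix.sample_ids)
    paired = build_paired_matrix(
        matrix, pairs, aligned, config.include_self_columns
    )
    corrected = remove_pairing_effects(paired)
    return condense(corrected, matrix.sample_ids)
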