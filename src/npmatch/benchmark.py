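"""Hermetic multi-method, multi-dataset benchmark harness.

Runs each correction method on each dataset, computes the per-dataset
metrics and integrated score (uncorrected reference scores exactly 1), and
aggregates methods by mean rank. All comparator methods are internal:
``none`` (uncorrected), ``npm`` (nearest-pair matching, phenotype only),
``linear`` (known-batch linear removal with protected phenotype), and
``mean_center`` (known-batch per-batch mean centering). Methods needing
batch labels are skipped, with a warning, on datasets lacking them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import pandas as pd

from .containers import ExpressionMatrix, SampleAnnotation, ValidationError
from .core import NpmConfig, npm_correct
from .linear import mean_center_batches, remove_batch_linear
from .metrics import MetricsReport, evaluate, integrated_score, mean_rank

KNOWN_BATCH_METHODS = {"linear", "mean_center"}
ALL_METHODS = ("none", "npm", "linear", "mean_center")


def correct_with(
    method: str,
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    config: NpmConfig | None = None,
) -> ExpressionMatrix:
    """Dispatch one correction method; ``none`` returns the input copy."""
    if method == "none":
        return matrix.copy()
    if method == "npm":
        return npm_correct(matrix, annotation, config)
    if method == "linear":
        return remove_batch_linear(matrix, annotation=annotation)
    if method == "mean_center":
        if annotation.batch is None:
            raise ValidationError("mean_center needs batch labels")
        return mean_center_batches(matrix, annotation.aligned_to(matrix).batch)
    raise ValidationError(f"unknown method {method!r}; choose from {ALL_METHODS}")


def run_benchmark(
    datasets: dict[str, tuple[ExpressionMatrix, SampleAnnotation]],
    methods: tuple[str, ...] = ALL_METHODS,
    config: NpmConfig | None = None,
) -> dict:
    """Full method × dataset grid of metrics, scores, and mean ranks.

    Returns a report dict: per-dataset per-method MetricsReport fields
    (including ``score``), the score grid, mean ranks, and any skips.
    """
    per_dataset: dict[str, dict[str, dict]] = {}
    scores: dict[str, dict[str, float]] = {m: {} for m in methods}
    skipped: list[dict] = []
    for ds_name, (matrix, annotation) in datasets.items():
        aligned = annotation.aligned_to(matrix)
        reference = evaluate(matrix, aligned, method_name="none")
        reference.score = 1.0
        per_dataset[ds_name] = {}
        for method in methods:
            if method in KNOWN_BATCH_METHODS and aligned.batch is None:
                warnings.warn(
                    f"skipping {method} on {ds_name}: no batch labels",
                    stacklevel=2,
                )
                skipped.append({"dataset": ds_name, "method": method})
                continue
            if method == "none":
                report = reference
            else:
                corrected = correct_with(method, matrix, aligned, config)
                report = evaluate(corrected, aligned, method_name=method)
                report.score = integrated_score(report, reference)
            per_dataset[ds_name][method] = report.to_dict()
            scores[method][ds_name] = report.score
    grid = pd.DataFrame(scores).T  # methods × datasets
    complete = grid.dropna(axis=0)
    ranks = mean_rank(complete) if complete.shape[0] >= 2 else pd.Series(dtype=float)
    return {
        "datasets": per_dataset,
        "scores": grid.to_dict(),
        "mean_rank": {str(k): float(v) for k, v in ranks.items()},
        "skipped": skipped,
    }


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
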