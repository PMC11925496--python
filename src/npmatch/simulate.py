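"""Synthetic batched expression data with known ground truth.

The generator works directly on the log2 scale — the scale the correction
consumes — as an additive Gaussian model:

    value[g, s] = baseline_g + DE shift (if g is a DE gene and s is in the
                  shifted class) + batch shift (if g is batch-affected)
                  + N(0, noise_sd)

Per-gene baselines are N(7, 2) (typical log2 expression magnitudes).
Batch shifts are drawn once per (gene, batch) from N(0, batch_effect_sd)
on a random subset of genes; phenotype shifts add de_effect to one
designated class per DE gene. Batch assignment mixes a deterministic
phenotype→batch map with uniform assignment: at ``confounding`` = 0
batches are independent of phenotype, at 1 they are fully confounded.

A count-level companion (Poisson sampling of 2^value) exists solely so the
preprocessing chain can be exercised on raw-count-like input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import ExpressionMatrix, SampleAnnotation, ValidationError


@dataclass
class SimConfig:
    """Study-condition knobs for one simulated dataset."""

    p: int = 2000
    n: int = 60
    c: int = 2
    n_batches: int = 3
    de_fraction: float = 0.05
    de_effect: float = 1.0
    batch_fraction: float = 0.3
    batch_effect_sd: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    confounding: float = 0.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        for frac in ("de_fraction", "batch_fraction", "confounding"):
            v = getattr(self, frac)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{frac} must lie in [0, 1]; got {v}")
        if self.c < 2:
            raise ValidationError("need at least 2 phenotype classes")
        if self.n < 2 * self.c:
            raise ValidationError(
                f"n={self.n} too small for c={self.c} classes (need ≥ 2 each)"
            )
        if self.n_batches < 1:
            raise ValidationError("need at least 1 batch")
        if self.confounding == 1.0:
            import warnings

            warnings.warn(
                "confounding=1: batch fully determined by phenotype; the "
                "simulation is unidentifiable for any correction method",
                stacklevel=2,
            )


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    de_genes: list[str]
    de_target_class: dict[str, str]
    batch_genes: list[str]
    batch_shifts: dict[str, list[float]]  # gene -> shift per batch
    batch_labels: list[str]
    config: dict

    def to_dict(self) -> dict:
        return asdict(self)


def simulate(config: SimConfig) -> tuple[ExpressionMatrix, SampleAnnotation, SimTruth]:
    """Draw one dataset; fully reproducible from ``config.seed``.

    Phenotype classes are assigned round-robin (balanced up to remainder).
    The annotation carries the true batch labels for evaluation.
    """
    rng = np.random.default_rng(config.seed)
    p, n, c = config.p, config.n, config.c
    feature_ids = [f"gene{i+1}" for i in range(p)]
    sample_ids = [f"sample{j+1}" for j in range(n)]
    classes = [f"class{j+1}" for j in range(c)]
    phenotype = np.asarray([classes[j % c] for j in range(n)], dtype=object)

    # batch assignment: deterministic phenotype->batch map, diluted by
    # uniform assignment at rate 1 - confounding
    batches = [f"batch{b+1}" for b in range(config.n_batches)]
    det = np.asarray(
        [batches[classes.index(ph) % config.n_batches] for ph in phenotype],
        dtype=object,
    )
    uniform = rng.choice(batches, size=n)
    use_det = rng.random(n) < config.confounding
    batch = np.where(use_det, det, uniform)
    # guarantee every batch is populated so evaluation silhouettes are defined
    for b, name in enumerate(batches):
        if not np.any(batch == name):
            batch[rng.integers(n)] = name

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(p, n))

    n_de = int(round(config.de_fraction * p))
    de_idx = rng.choice(p, size=n_de, replace=False)
    de_idx.sort()
    de_target: dict[str, str] = {}
    for g in de_idx:
        target = classes[1] if c == 2 else classes[int(rng.integers(1, c))]
        de_target[feature_ids[g]] = target
        values[g, phenotype == target] += config.de_effect

    n_batch_genes = int(round(config.batch_fraction * p))
    bg_idx = rng.choice(p, size=n_batch_genes, replace=False)
    bg_idx.sort()
    shifts: dict[str, list[float]] = {}
    batch_pos = {name: np.flatnonzero(batch == name) for name in batches}
    for g in bg_idx:
        per_batch = rng.normal(0.0, config.batch_effect_sd, size=config.n_batches)
        shifts[feature_ids[g]] = [float(x) for x in per_batch]
        for b, name in enumerate(batches):
            values[g, batch_pos[name]] += per_batch[b]

    matrix = ExpressionMatrix(values, feature_ids, sample_ids, is_log=True)
    annotation = SampleAnnotation(sample_ids, phenotype, batch)
    truth = SimTruth(
        de_genes=[feature_ids[g] for g in de_idx],
        de_target_class=de_target,
        batch_genes=[feature_ids[g] for g in bg_idx],
        batch_shifts=shifts,
        batch_labels=[str(b) for b in batch],
        config=asdict(config),
    )
    return matrix, annotation, truth


def simulate_counts(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SimTruth]:
    """Poisson count companion: counts ~ Poisson(2^value − 1).

    Intended only to feed the preprocessing chain; the Poisson layer uses
    its own stream so the log-scale dataset is unchanged.
    """
    matrix, annotation, truth = simulate(config)
    rng = np.random.default_rng(config.seed + 1_000_003)
    lam = np.maximum(np.exp2(matrix.values) - 1.0, 0.0)
    counts = rng.poisson(lam).astype(float)
    return (
        ExpressionMatrix(counts, matrix.feature_ids, matrix.sample_ids, is_log=False),
        annotation,
        truth,
    )


def scenario_suite() -> list[SimConfig]:
    """Named scenarios spanning sample sizes and batch/phenotype balance."""
    return [
        SimConfig(name="balanced", seed=101),
        SimConfig(name="unbalanced-batches", seed=202, n_batches=4, confounding=0.3),
        SimConfig(name="confounded", seed=303, confounding=0.8, n_batches=2),
        SimConfig(name="tiny", seed=404, n=8, n_batches=2, p=1000),
        SimConfig(name="multi-class", seed=505, c=3, n=36, n_batches=2),
    ]
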