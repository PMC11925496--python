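import numpy as np
import pytest

from npmatch import ExpressionMatrix, SampleAnnotation


def make_matrix(values, feature_ids=None, sample_ids=None, is_log=True):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return ExpressionMatrix(
        values,
        feature_ids or [f"g{i+1}" for i in range(p)],
        sample_ids or [f"s{j+1}" for j in range(n)],
        is_log,
    )


def make_annotation(phenotype, sample_ids=None, batch=None):
    n = len(phenotype)
    return SampleAnnotation(sample_ids or [f"s{j+1}" for j in range(n)], phenotype, batch)


@pytest.fixture
def toy_matrix():
    """3 features × 4 samples, two phenotype classes."""
    return make_matrix(
        [[1.0, 3.0, 5.0, 7.0], [2.0, 2.0, 8.0, 8.0], [0.0, 1.0, 0.0, 1.0]]
    )


@pytest.fixture
def toy_annotation():
    return make_annotation(["A", "A", "B", "B"])


# Deterministic fixture recipes shared with the external reference runs
# whose outputs are frozen in the test modules. The draw order matters.


def reference_fixtures():
    rng = np.random.RandomState(20240915)
    q = np.round(rng.uniform(0, 10, size=(6, 4)), 1)
    q[2, 1] = q[0, 1]
    q[4, 3] = q[1, 3]
    rb = rng.normal(5, 1, size=(5, 8))
    rb[:, [2, 3, 6, 7]] += 1.5
    eb = rng.normal(6, 1, size=(30, 6))
    eb[:5, 3:] += rng.uniform(0.5, 2.0, size=(5, 1))
    return q, rb, eb


def heteroscedastic_fixture():
    rng = np.random.RandomState(77)
    sd = rng.uniform(0.2, 3.0, size=40)
    eb2 = 6 + rng.normal(0, 1, size=(40, 8)) * sd[:, None]
    eb2[:6, 4:] += 1.2
    return eb2
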