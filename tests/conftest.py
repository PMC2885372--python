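import numpy as np
import pytest

from ema import ExpressionDataset


def make_dataset(values, labels, gene_prefix="g", sample_prefix="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, d = values.shape
    return ExpressionDataset(
        values=values,
        labels=np.asarray(labels, dtype=int),
        gene_ids=np.array([f"{gene_prefix}{k}" for k in range(d)], dtype=object),
        sample_ids=np.array([f"{sample_prefix}{j}" for j in range(n)], dtype=object),
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def separable_ds():
    """Ten samples, three genes; gene 0 separates the classes perfectly."""
    rng = np.random.default_rng(42)
    labels = np.r_[np.full(5, -1), np.full(5, 1)]
    values = rng.uniform(0, 1, (10, 3))
    values[:, 0] = np.where(labels == 1, 2.0, -2.0) + rng.normal(0, 0.1, 10)
    return make_dataset(values, labels)
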