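import numpy as np
import pandas as pd
import pytest

from coexnet import ExpressionMatrix, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, two batches, no missing data."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, 1.5, 0.5, 1.5]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    batches = pd.Series(["b1", "b1", "b2", "b2"], index=values.columns)
    return ExpressionMatrix(values=values, batches=batches)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 5 modules x 40 genes, 100 background
    genes, 60 samples."""
    return generate_dataset(SyntheticConfig(seed=42))


def random_expression(rng, n_genes=10, n_samples=20):
    values = pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(values=values, batches=pd.Series("b", index=values.columns))
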