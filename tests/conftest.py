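import numpy as np
import pandas as pd
import pytest

from subtypeforge import (
    SimConfig,
    median_center_genes,
    select_top_variable_genes,
    simulate_subtyped_expression,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small 4-subtype cohort with clearly recoverable structure."""
    return SimConfig(n_samples=48, n_genes=300, n_subtypes=4,
                     n_informative_genes_per_subtype=20,
                     effect_size=2.0, noise_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    matrix, labels = simulate_subtyped_expression(small_config)
    return matrix, labels


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    matrix, labels = small_cohort
    top = select_top_variable_genes(median_center_genes(matrix), 150)
    return top, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def toy_matrix(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)
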