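import numpy as np
import pandas as pd
import pytest

from triadex import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact study-design configuration used across test modules."""
    return SimConfig(seed=42, n_genes=400)


@pytest.fixture(scope="session")
def sim_data(small_config):
    """(CountMatrix, SampleSheet, truth) for the default 7-genotype design."""
    return simulate_counts(small_config)


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    c = rng.negative_binomial(20, 20 / 120, size=(50, 6))
    return pd.DataFrame(
        c, index=[f"g{i}" for i in range(50)], columns=list("abcdef")
    )
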