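import numpy as np
import pandas as pd
import pytest

from omicpred import SimConfig, simulate_dataset
from omicpred.datatypes import FeatureMatrix


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_inbreds=22, n_variants=300, n_genes=60, n_metabolites=12,
        n_environments=3, reps_per_env=4, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_fm(values, layer="SV", samples=None, features=None, meta=None) -> FeatureMatrix:
    values = np.asarray(values, float)
    n, m = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    features = features or [f"f{j}" for j in range(m)]
    df = pd.DataFrame(values, index=samples, columns=features)
    if meta is not None:
        meta = pd.DataFrame(meta, index=features)
    return FeatureMatrix(df, layer, meta)
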