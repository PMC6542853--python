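import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import comboseq as cs

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """A small factorial simulation with regulated genes in every class."""
    params = cs.SimulationParams(
        n_genes=400, frac_A_only=0.15, frac_B_only=0.1, frac_both=0.05, seed=3
    )
    truth, counts, design = cs.simulate_dataset(params)
    return params, truth, counts, design


@pytest.fixture(scope="session")
def fitted(small_dataset):
    _, _, counts, design = small_dataset
    return cs.NBFactorialModel(counts, design).fit()


@pytest.fixture()
def single_condition_design():
    """Factory: a one-condition design frame with n samples named s0..s{n-1}."""

    def make(n, condition="VEHICLE"):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "condition": [condition] * n,
                "replicate": list(range(1, n + 1)),
            }
        )

    return make


@pytest.fixture()
def unit_size_factors():
    def make(sample_ids):
        return pd.Series(np.ones(len(sample_ids)), index=list(sample_ids))

    return make
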