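import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from occubiome.simulate import SimulationConfig, simulate_study
from occubiome.tables import FeatureTable


@pytest.fixture(scope="session")
def small_study():
    """A small informative study shared across read-only tests."""
    config = SimulationConfig(
        n_per_group=10, n_features=40, n_informative=3, depth_mean=20_000, seed=101
    )
    table, metadata, truth = simulate_study(config)
    return config, table, metadata, truth


@pytest.fixture()
def toy_table():
    counts = pd.DataFrame(
        {
            "s1": [5, 0, 3, 2],
            "s2": [0, 1, 4, 5],
            "s3": [2, 2, 2, 2],
            "s4": [9, 0, 0, 1],
        },
        index=["fA", "fB", "fC", "fD"],
    )
    return FeatureTable(counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
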