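import numpy as np
import pandas as pd
import pytest

from magblup.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic herd shared by integration-flavoured tests."""
    cfg = SimulationConfig(
        n_animals=60,
        n_sires_extra=6,
        n_snps=300,
        n_mg=25,
        depth_range=(5_000, 20_000),
        seed=7,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def composition_10x5(rng):
    """Strictly positive 10-sample x 5-part composition table."""
    x = rng.dirichlet(np.full(5, 2.0), size=10)
    return pd.DataFrame(
        x,
        index=[f"s{i}" for i in range(10)],
        columns=[f"K{j:05d}" for j in range(1, 6)],
    )
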