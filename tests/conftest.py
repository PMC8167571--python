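import numpy as np
import pandas as pd
import pytest

from eisacerna import SimConfig, default_design, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """One small full-design simulation shared across read-only tests."""
    cfg = SimConfig(n_genes=400, seed=11)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def two_group_design():
    return default_design(cell_lines=("U2932",), timepoints=(8,), n_reps=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_counts():
    """Deterministic 6-gene, 4-sample count matrix."""
    return pd.DataFrame(
        {
            "s1": [100, 250, 40, 900, 12, 0],
            "s2": [120, 230, 35, 950, 15, 0],
            "s3": [90, 260, 50, 880, 10, 0],
            "s4": [110, 240, 45, 920, 14, 0],
        },
        index=[f"g{i}" for i in range(6)],
    )
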