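import numpy as np
import pandas as pd
import pytest

from senescan import PlantedSweep, SimConfig


@pytest.fixture
def small_genome_config():
    return SimConfig(
        seed=11,
        arms=[("X", 1_000_000, 400)],
        sweeps=[PlantedSweep("X", 200_000, 320_000, 0.9)],
    )


@pytest.fixture
def tiny_variants():
    """Hand-written 3-variant table on one arm."""
    return pd.DataFrame(
        {
            "arm": ["X", "X", "X"],
            "pos": [100, 250, 900],
            "freq_sel_1": [0.9, 0.8, 0.1],
            "freq_sel_2": [1.0, 0.9, 0.2],
            "freq_ctl_1": [0.1, 0.2, 0.1],
            "freq_ctl_2": [0.0, 0.1, 0.2],
        }
    )


def variants_from_dp(dp, positions=None, arm="X"):
    """Build a minimal variant table carrying the given delta_p sequence."""
    n = len(dp)
    pos = list(positions) if positions is not None else [100 * (i + 1) for i in range(n)]
    return pd.DataFrame(
        {
            "arm": [arm] * n,
            "pos": pos,
            "freq_sel_1": list(dp),
            "freq_ctl_1": [0.0] * n,
            "delta_p": list(dp),
        }
    )


@pytest.fixture
def dp_table_builder():
    return variants_from_dp


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
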