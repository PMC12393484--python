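import numpy as np
import pytest

from tfscope.synthetic import (
    FeatureSimParams,
    FfsSimParams,
    simulate_feature_table,
    simulate_ffs_stack,
)


@pytest.fixture(scope="session")
def monomer_stack():
    """Pure-monomer fluctuation stack, eps = 0.5, bleach-free."""
    params = FfsSimParams(
        epsilon_monomer=0.5, species_mix=[(1, 2.0)], n_frames=100,
        shape=(64, 64), seed=101,
    )
    return simulate_ffs_stack(params)


@pytest.fixture(scope="session")
def two_condition_table():
    """Well-separated two-condition Gaussian feature table."""
    params = FeatureSimParams(
        conditions=["ctrl", "treated"], n_cells_per_condition=300,
        n_features=20, effect_size=3.0, seed=202,
    )
    table, truth = simulate_feature_table(params)
    return table, truth
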