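import numpy as np
import pytest

import cortexflow as cf


@pytest.fixture(scope="session")
def hierarchy():
    return cf.make_label_hierarchy(seed=0)


@pytest.fixture(scope="session")
def small_config():
    """Small but statistically meaningful simulation for fast unit tests."""
    return cf.SimConfig(
        n_train=150,
        n_val=60,
        voxels_per_area=10,
        feature_dims=(16, 24),
        sparsity_k=2,
        snr=10.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_sequences(hierarchy):
    """Strong-marginal-signal sequences on which decoders should learn."""
    config = cf.SimConfig(
        n_train=300,
        n_val=120,
        voxels_per_area=12,
        beta_marginal=(4.0, 4.3, 4.6, 4.9, 5.2),
        beta_relational=0.5,
        snr=10.0,
        seed=1,
    )
    train, val, _ = cf.simulate_area_sequences(config, hierarchy)
    return train, val
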