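import numpy as np
import pytest

import snyq


@pytest.fixture(scope="session")
def layout():
    return snyq.make_layout(seed=0)


@pytest.fixture(scope="session")
def tiny_layout():
    """A 4x4 grid (16 electrodes) for fast simulation tests."""
    return snyq.make_layout(seed=0, n_cols=4, n_rows=4)


@pytest.fixture(scope="session")
def tiny_sim_cfg():
    return snyq.SimulationConfig(
        seed=3, n_trials_per_condition=10, n_subjects=2
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
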