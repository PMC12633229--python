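import numpy as np
import pytest

import anchoromics as am


@pytest.fixture(scope="session")
def small_dataset():
    """Compact simulated dataset shared by read-only tests."""
    cfg = am.SimConfig(seed=11)
    cfg.n_per_group = {"Control": 40, "MCI": 30, "AD": 40, "Other": 0}
    cfg.n_genes = 400
    for m in cfg.module_specs:
        m.size = 20
    return am.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
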