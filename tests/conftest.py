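import numpy as np
import pytest

import diopower as dp


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = dp.SimulationConfig(n_mice_per_arm=10, n_zotus=80, seed=42)
    return dp.generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
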