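import numpy as np
import pytest

import mitocharter as mc


@pytest.fixture(scope="session")
def erumphii():
    """The packaged 37-feature reference annotation (15,795 bp circle)."""
    return mc.load_erumphii()


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic simulated genome shared across tests."""
    return mc.simulate_genome(mc.GenomeSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20221107)
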