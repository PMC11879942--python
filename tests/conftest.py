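import numpy as np
import pytest

from ivpglab import synthetic


@pytest.fixture(scope="session")
def default_config() -> synthetic.SimConfig:
    return synthetic.SimConfig()


@pytest.fixture(scope="session")
def cohort99(default_config):
    """Default-seed full cohort: (table, maps, truths)."""
    return synthetic.generate_cohort(default_config)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One animal per group x pattern cell, for fast schema/stats checks."""
    cfg = synthetic.SimConfig(
        seed=3, group_sizes={"Sham": (2, 2, 3), "HTN-CM": (2, 2, 3)}
    )
    table, maps, truths = synthetic.generate_cohort(cfg)
    return table, maps, truths


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
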