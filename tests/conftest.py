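import numpy as np
import pytest

from myxphen.synthetic import SimulationConfig, simulate_trait_table


@pytest.fixture(scope="session")
def small_table():
    """31-strain table with planted effects, reused across read-only tests."""
    cfg = SimulationConfig(n_strains=31, rng_seed=5)
    return simulate_trait_table(cfg)


@pytest.fixture(scope="session")
def null_table_200():
    """Pure-null table at the library's scale: 200 mutants, no effects."""
    cfg = SimulationConfig(n_strains=201, effect_fraction=0.0, rng_seed=101)
    return simulate_trait_table(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
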