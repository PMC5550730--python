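import numpy as np
import pytest

from bgdbs.cell_models import CELL_TYPES, load_cell_params
from bgdbs.engine import SimulationConfig, run_simulation


@pytest.fixture(scope="session")
def cells():
    return {ct: load_cell_params(ct) for ct in CELL_TYPES}


@pytest.fixture(scope="session")
def micro_result():
    """Small healthy network run shared across engine/metric tests."""
    cfg = SimulationConfig(n_per_pop=10, duration=400.0, seed=7,
                           record_voltages=4, record_stride=1)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def pd_small_result():
    """Small PD network run (no DBS) shared across tests."""
    cfg = SimulationConfig(n_per_pop=16, duration=1000.0, seed=11,
                           condition="pd")
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
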