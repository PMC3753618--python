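import pytest

import locusdrift as ld


@pytest.fixture(scope="session")
def split_config():
    return ld.SimulationConfig(n_cells=80, seed=11)


@pytest.fixture(scope="session")
def split_raw(split_config):
    """Unsynchronized full-cycle ensemble (80 cells, default conditions)."""
    return ld.simulate_split_cycle(split_config)


@pytest.fixture(scope="session")
def split_synced(split_raw):
    """Synchronized + oriented full-cycle ensemble."""
    return ld.orient(ld.synchronize(split_raw))
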