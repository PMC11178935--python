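import numpy as np
import pandas as pd
import pytest

from mtwdbn.spiking import SpikeData, make_laminar_spec, simulate_network
from mtwdbn.tables import bin_and_slice


@pytest.fixture(scope="session")
def laminar_spec():
    return make_laminar_spec()


@pytest.fixture(scope="session")
def laminar_spikes(laminar_spec):
    """Moderate laminar simulation shared across tests."""
    return simulate_network(laminar_spec, n_trials=100, duration_ms=2000,
                            dt_ms=0.1, seed=42)


@pytest.fixture(scope="session")
def laminar_table(laminar_spikes):
    return bin_and_slice(laminar_spikes, 1.2, 2, 3)


@pytest.fixture()
def hand_spikes():
    """Two populations, one trial, known spike times for exact binning."""
    df = pd.DataFrame({
        "trial": [0, 0, 0, 0, 0, 0],
        "unit": ["a", "a", "a", "b", "b", "a"],
        "time_ms": [0.5, 1.5, 1.7, 2.5, 3.1, 4.9],
    })
    return SpikeData(df, {"a": "A", "b": "B"}, n_trials=1, duration_ms=5.0)


@pytest.fixture()
def coupled_table():
    """Table where the effect's lag-0 column copies a cause lag-1 column."""
    rng = np.random.default_rng(0)
    n = 4000
    a = rng.integers(0, 2, size=n + 2)
    vals = np.zeros((n, 6), dtype=np.int8)
    # columns: A@-2.4, A@-1.2, A@0, B@-2.4, B@-1.2, B@0
    vals[:, 0] = a[:n]
    vals[:, 1] = a[1:n + 1]
    vals[:, 2] = a[2:]
    vals[:, 5] = a[1:n + 1]  # B@0 copies A@-1.2 exactly
    vals[:, 4] = rng.integers(0, 2, size=n)
    vals[:, 3] = rng.integers(0, 2, size=n)
    from mtwdbn.tables import BinnedSlicedTable
    return BinnedSlicedTable(vals, ["A", "B"], [-2.4, -1.2, 0.0], 2, 1.2)
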