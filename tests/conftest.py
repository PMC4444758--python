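import numpy as np
import pytest

from bgspike import CircuitConfig, run_circuit
from bgspike.raster import SpikeRaster


@pytest.fixture(scope="session")
def small_run():
    """One cached 20x20 free run at mid dopamine (no GPi)."""
    cfg = CircuitConfig(
        shape=(20, 20), duration=500.0, da=0.5, seed=11,
        simulate_gpi=False,
    )
    return run_circuit(cfg)


@pytest.fixture
def random_raster():
    """A reproducible random Poisson raster for metric oracles."""
    rng = np.random.default_rng(42)
    n_neurons, duration, rate = 30, 1000.0, 20.0
    ids, times = [], []
    for j in range(n_neurons):
        n = rng.poisson(rate * duration / 1000.0)
        t = np.sort(rng.uniform(0, duration, n))
        ids.append(np.full(n, j))
        times.append(t)
    return SpikeRaster(
        np.concatenate(ids), np.concatenate(times), n_neurons, duration
    )
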