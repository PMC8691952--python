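import numpy as np
import pytest

from dendrite_credit import biophysics as B
from dendrite_credit import morphology as M


@pytest.fixture(scope="session")
def small_geom():
    return M.synthetic_tree(4, 2, depth=2, seed=0)


@pytest.fixture(scope="session")
def tiny_geom():
    return M.synthetic_tree(2, 1, depth=1, seed=0)


@pytest.fixture(scope="session")
def cable20():
    return M.uniform_cable(20, 400.0, 1.0)


@pytest.fixture
def active_spec():
    return B.BiophysicsSpec(mode="active")


@pytest.fixture
def passive_spec():
    return B.BiophysicsSpec(mode="passive")


@pytest.fixture
def leak_only_spec():
    return B.BiophysicsSpec(mode="passive", g_na_soma=0.0, g_k_soma=0.0,
                            g_km_soma=0.0)


@pytest.fixture
def small_layout(small_geom):
    return B.place_synapses(small_geom, 15, 5, seed=3,
                            w_e=0.3e-3, w_i=0.5e-3)


def random_trains(n_syn, horizon, seed, rate_hz=10.0):
    rng = np.random.default_rng(seed)
    return B.SpikeTrains([
        np.sort(rng.uniform(0, horizon,
                            rng.poisson(rate_hz * horizon / 1000.0)))
        for _ in range(n_syn)])
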