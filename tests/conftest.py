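import numpy as np
import pytest

from bioturb import LatticeState, ModelParams, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return SimConfig(d=8, w=12, d_lum=2, n_steps=5, seed=7)


@pytest.fixture
def small_params():
    return ModelParams(activity=0.5, distance=1.5, downwards=0.5,
                       range_frac=1.0, tracerdif=0.9)


def make_state(tracer, capacity):
    """Balanced LatticeState with the given per-layer tracer counts."""
    tracer = np.asarray(tracer, dtype=np.int64)
    nonmarked = capacity - tracer
    assert (nonmarked >= 0).all()
    return LatticeState(tracer.copy(), nonmarked, capacity)


def random_balanced_state(rng, d, w):
    tracer = rng.integers(0, w + 1, size=d)
    return make_state(tracer, w)


def point_release_state(d, w, layer, n_tracer):
    """Dilute tracer release in a single layer of an otherwise clean column."""
    tracer = np.zeros(d, dtype=np.int64)
    tracer[layer] = n_tracer
    return make_state(tracer, w)
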