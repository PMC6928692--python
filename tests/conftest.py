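import numpy as np
import pytest

import myoxray as mx


@pytest.fixture(scope="session")
def default_geometry():
    return mx.GeometryParams()


@pytest.fixture(scope="session")
def default_elastic():
    return mx.ElasticParams()


@pytest.fixture(scope="session")
def default_rates():
    return mx.RateParams()


@pytest.fixture()
def small_lattice():
    """Four thick / eight thin filaments, relaxed."""
    return mx.build_half_sarcomere(n_thick=4, seed=0)


@pytest.fixture(scope="session")
def uniform_profile_order2():
    """Noiseless diffraction of a relaxed 364-monomer filament around the
    second-order reflection."""
    z = mx.uniform_filament(364, 2.73)
    grid = mx.order_window_grid(2, 2.73)
    return mx.meridional_intensity([z], grid)


@pytest.fixture(scope="session")
def tiny_sim_trace():
    """One short isometric run shared by analysis tests (2 thick, 0.12 s)."""
    cfg = mx.SimulationConfig(geometry=mx.GeometryParams(n_thick=2),
                              snapshot_after_s=0.06, snapshot_every_s=0.02)
    return mx.run_isometric(cfg, 0.12, seed=7)


def approx_rel(value, rel):
    return pytest.approx(value, rel=rel)


def rng(seed=0):
    return np.random.default_rng(seed)
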