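import numpy as np
import pytest

from t1dsim import (ConfigurationError, ParameterSet, SimulationConfig,
                    build_world, grid_scale)
from t1dsim.world import BETA_APOPTOTIC, BETA_HEALTHY, ISLET


@pytest.mark.parametrize("diam,radius,expected", [
    (100, 38, 1.32),   # the default physical scale
    (76, 38, 1.00),    # diameter equal to the cell span
    (110, 38, 1.45),
])
def test_grid_scale(diam, radius, expected):
    assert grid_scale(diam, radius) == expected


@pytest.mark.parametrize("diam,radius", [(0, 38), (100, 0), (-5, 38)])
def test_grid_scale_rejects_nonpositive(diam, radius):
    with pytest.raises(ValueError):
        grid_scale(diam, radius)


@pytest.fixture(scope="module")
def reduced_world():
    cfg = SimulationConfig(n_islets=5, islet_radius=10, n_beta_cells=320,
                           params=ParameterSet(init_apoptotic_beta=20))
    return cfg, build_world(cfg, rng_seed=7)


def test_beta_count_exact(reduced_world):
    cfg, w = reduced_world
    assert len(w.beta_pos) == cfg.n_beta_cells
    assert np.count_nonzero(w.beta_status == BETA_APOPTOTIC) == 20
    assert np.count_nonzero(w.beta_status == BETA_HEALTHY) == 300


def test_beta_within_islet_disks(reduced_world):
    """Every beta patch lies within islet_radius of some islet centre."""
    cfg, w = reduced_world
    d2 = ((w.beta_pos[:, None, :] - w.islet_centers[None, :, :]) ** 2).sum(-1)
    assert (d2.min(axis=1) <= cfg.islet_radius ** 2).all()
    assert (w.region[w.beta_pos[:, 0], w.beta_pos[:, 1]] == ISLET).all()


def test_region_map_partitions_grid(reduced_world):
    _, w = reduced_world
    assert set(np.unique(w.region)) == {0, 1, 2}
    assert w.region.shape == (201, 201)


def test_rebuild_same_seed_identical(reduced_world):
    cfg, w = reduced_world
    w2 = build_world(cfg, rng_seed=7)
    assert np.array_equal(w.region, w2.region)
    assert np.array_equal(w.beta_pos, w2.beta_pos)
    assert np.array_equal(w.beta_status, w2.beta_status)
    assert np.array_equal(w.beta_quiesc, w2.beta_quiesc)
    assert w.onset_threshold_frac == w2.onset_threshold_frac


def test_quiescence_clocks_staggered(reduced_world):
    _, w = reduced_world
    T0 = w.config.params.quiescence_T0_h
    assert (w.beta_quiesc >= 0).all() and (w.beta_quiesc <= T0).all()
    assert w.beta_quiesc.std() > 10  # genuinely staggered, not constant


def test_onset_threshold_in_band(reduced_world):
    cfg, w = reduced_world
    assert cfg.onset_fraction_low <= w.onset_threshold_frac <= cfg.onset_fraction_high


def test_overfull_islets_rejected():
    cfg = SimulationConfig(n_islets=1, islet_radius=3, n_beta_cells=500)
    with pytest.raises(ConfigurationError):
        build_world(cfg, rng_seed=0)


def test_zero_islets_rejected_when_beta_requested():
    cfg = SimulationConfig(n_islets=0, n_beta_cells=10)
    with pytest.raises(ConfigurationError):
        build_world(cfg, rng_seed=0)


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(onset_fraction_low=0.5, onset_fraction_high=0.2).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(grid_width=20, islet_radius=38).validate()


def test_initial_agents_placed(reduced_world):
    """Resident DCs sit in islet disks; the naive pool sits in the PLN."""
    _, w = reduced_world
    p = w.config.params
    assert len(w.agents["dc"]) == p.n_resident_dc
    assert len(w.agents["naiveT"]) == p.n_naive_pool
    for a in w.agents["dc"]:
        assert w.disk_mask[a.y, a.x]
    lo, hi = p.naive_lifespan_d
    for a in w.agents["naiveT"]:
        assert w.region[a.y, a.x] == 2
        assert lo * 24 <= a.lifespan_h <= hi * 24
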