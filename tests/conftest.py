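import pytest

from t1dsim import ParameterSet, SimulationConfig, mini_world


@pytest.fixture(scope="session")
def mini_cfg() -> SimulationConfig:
    """Default desk-scale world: 5 islets x 64 cells = 320 beta cells."""
    return mini_world()


@pytest.fixture(scope="session")
def quiet_cfg() -> SimulationConfig:
    """A world with no autoimmune trigger and no immune cells."""
    params = ParameterSet(init_apoptotic_beta=0, n_naive_pool=0,
                          n_resident_dc=0)
    return SimulationConfig(n_islets=2, islet_radius=6, n_beta_cells=50,
                            params=params)


@pytest.fixture(scope="session")
def aggressive_cfg(mini_cfg) -> SimulationConfig:
    """Hot parameters: long-lived CTLs, big trigger, strong recruitment."""
    params = mini_cfg.params.replace(
        ctl_lifespan_h=180.0, init_apoptotic_beta=40, dc_recruit_mu=1e-4)
    return mini_cfg.replace(params=params)
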