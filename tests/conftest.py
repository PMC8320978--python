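import numpy as np
import pytest

import betamev as bm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario1_cfg():
    return bm.ScenarioConfig(scenario=1, n=40, kx=0.75, gamma1=2.8, R=1, seed=42)


@pytest.fixture(scope="session")
def scenario1_draw(scenario1_cfg):
    """One fixed scenario-1 dataset plus its model and truth."""
    spec, truth = bm.scenario_model(scenario1_cfg)
    ds = bm.generate_scenario(scenario1_cfg, 0)
    return spec, truth, ds, scenario1_cfg


@pytest.fixture(scope="session")
def scenario2_draw():
    cfg = bm.ScenarioConfig(scenario=2, n=60, kx=0.75, R=1, seed=7)
    spec, truth = bm.scenario_model(cfg)
    ds = bm.generate_scenario(cfg, 0)
    return spec, truth, ds, cfg


@pytest.fixture(scope="session")
def scenario3_draw():
    cfg = bm.ScenarioConfig(scenario=3, n=60, kx=0.75, R=1, seed=9)
    spec, truth = bm.scenario_model(cfg)
    ds = bm.generate_scenario(cfg, 0)
    return spec, truth, ds, cfg
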