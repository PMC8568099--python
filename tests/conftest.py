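import numpy as np
import pytest

import crxsim as cx
from crxsim.schedules import PoolConfig


@pytest.fixture(scope="session")
def small_world():
    """A 200-agent world for fast unit tests."""
    cfg = cx.DemographicConfig(
        n_agents=200, n_households=80, n_workplaces=10, n_schools=2,
        n_clinics=2, n_resource_sites=40,
    )
    return cx.generate_world(cfg, seed=11)


@pytest.fixture(scope="session")
def small_pool():
    return cx.build_synthetic_pool(PoolConfig(max_templates=5), seed=7)


@pytest.fixture(scope="session")
def tiny_world():
    """5 agents on a handful of places, for straight-line oracle checks."""
    cfg = cx.DemographicConfig(
        n_agents=5, n_households=2, n_workplaces=1, n_schools=1,
        n_clinics=1, n_resource_sites=4, bounding_box=(0.0, 0.0, 4.0, 4.0),
    )
    return cx.generate_world(cfg, seed=3)


@pytest.fixture(scope="session")
def busy_pool():
    """Schedule pool with frequent clinic visits and decisions, so short
    runs exercise every event type."""
    cfg = PoolConfig(max_templates=4, health_maintenance_rate=0.15,
                     medical_visit_weekday_rate=0.5, out_of_home_rate=0.35)
    return cx.build_synthetic_pool(cfg, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
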