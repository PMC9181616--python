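import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import larvagrow as lg

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: Published biphasic parameter sets (μm, /d) used as generator truth.
TABLE3 = {
    13.0: dict(L_inf=595.83, b=0.107, c_fed=0.012, c_nonfed=0.010, t_b=21.0),
    15.0: dict(L_inf=481.59, b=0.263, c_fed=0.013, c_nonfed=0.005, t_b=17.0),
    17.0: dict(L_inf=512.61, b=0.216, c_fed=0.006, c_nonfed=0.006, t_b=17.0),
}


@pytest.fixture(scope="session")
def params15():
    p = TABLE3[15.0]
    return lg.BiphasicParams(
        L_inf=p["L_inf"], b=p["b"], L0=176.0, t_b=p["t_b"],
        c_fed=p["c_fed"], c_nonfed=p["c_nonfed"],
    )


@pytest.fixture(scope="session")
def params13():
    p = TABLE3[13.0]
    return lg.BiphasicParams(
        L_inf=p["L_inf"], b=p["b"], L0=176.0, t_b=p["t_b"],
        c_fed=p["c_fed"], c_nonfed=p["c_nonfed"],
    )


@pytest.fixture(scope="session")
def thermal_truth():
    return lg.ThermalParams(t_a=6661.79, t_ref=293.15, t_ah=82380.0, t_h=294.44)


@pytest.fixture(scope="session")
def cohort15():
    """One reproducible 15°C cohort (both food conditions)."""
    cfg = lg.default_cohort_config(15.0, seed=421)
    return lg.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_start_grid():
    """Four well-spread starts; enough for the well-posed synthetic fits."""
    return [(500, 0.3, 0.005), (500, 0.1, 0.02), (800, 0.3, 0.02), (800, 0.1, 0.005)]


def rng_seeds(master: int, count: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=count)]
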