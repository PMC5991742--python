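import numpy as np
import pytest

from volescr.data import EncounterData, TrapArray, build_state_space
from volescr.detection import DetectionParams, IndicatorConfig
from volescr.simulate import SimOptions, june_grid, simulate_captures, \
    simulate_population


@pytest.fixture
def toy_traps() -> TrapArray:
    """Five traps in a cross: centre at origin, four arms at 10 m."""
    return TrapArray(
        detector_id=np.array(["c", "n", "s", "e", "w"], dtype=object),
        x=np.array([0.0, 0.0, 0.0, 10.0, -10.0]),
        y=np.array([0.0, 10.0, -10.0, 0.0, 0.0]),
        node_id=np.array(["c", "n", "s", "e", "w"], dtype=object))


@pytest.fixture
def toy_data() -> EncounterData:
    """Three individuals over K=4: one site-faithful, one moving between
    two traps, one that died in trap on occasion 2."""
    y = np.array([
        [0, -1, 0, -1],
        [1, 3, -1, 3],
        [2, 2, -1, -1],
    ])
    return EncounterData(y=y,
                         sex=np.array([0, 1, -1]),
                         removal_occasion=np.array([-1, -1, 1]))


@pytest.fixture(scope="session")
def june_setup():
    """June-style grid, 30 m buffered state space and truth parameters."""
    traps = june_grid()
    space = build_state_space(traps, buffer=30.0, pixel_side=1.2)
    params = DetectionParams(alpha0_f=-1.92, alpha0_m=-2.74,
                             alpha_time=0.28, alpha_behav=0.0,
                             sigma_f=4.1, sigma_m=8.12)
    return traps, space, params


@pytest.fixture(scope="session")
def june_dataset(june_setup):
    """One synthetic June-like dataset (N=150, single-catch, deaths)."""
    traps, space, params = june_setup
    pop = simulate_population(space, 60.0, 0.25, params, seed=7,
                              fixed_n=150)
    data = simulate_captures(pop, traps, SimOptions(K=8, seed=8))
    return pop, data


@pytest.fixture
def null_cfg() -> IndicatorConfig:
    return IndicatorConfig(w_time=0, w_behav=0, w_sex=0, sex_sigma=0)
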