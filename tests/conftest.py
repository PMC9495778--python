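import numpy as np
import pytest

from dynsdm.ecology import (
    DemographyParams,
    DispersalParams,
    InitialPopulationParams,
    SuitabilityParams,
)
from dynsdm.lattice import EnvSeries, build_rect_grid
from dynsdm.synthetic import ScenarioConfig, generate_study


@pytest.fixture(scope="session")
def desk_bundle():
    """The default desk-scale synthetic study, shared across tests."""
    return generate_study(seed=11)


@pytest.fixture
def small_setup():
    """A 3x3 homogeneous setup for hand-checkable simulations."""
    grid = build_rect_grid(3, 3, 1.0)
    T = 10
    years = 2000 + np.arange(T)
    x = np.zeros((9, T, 1))
    urban = np.full((9, T), 0.3)
    env = EnvSeries(years, x, urban)
    demog = DemographyParams(rho=0.3, phi=200.0, k_hat=3.0, theta=6.0, M=40.0)
    disp = DispersalParams(ds=0.2, dl=0.05)
    suit = SuitabilityParams(np.array([0.5, 0.0]))  # p = expit(0.5) everywhere
    init = InitialPopulationParams(
        cells=np.array([4]), pop_ini=np.array([40.0]), age_ratio=np.array([0.3])
    )
    return dict(grid=grid, env=env, demog=demog, disp=disp, suit=suit,
                init=init, K=8)
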