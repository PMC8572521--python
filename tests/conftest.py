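import numpy as np
import pytest

from phagestrat import (
    ModelParams,
    SimulationSpec,
    StrategyKind,
    run_simulation,
)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def fig3_trajectories(default_params):
    """The four baseline scenarios at N0=2: no phage, lytic, PtW, PtL."""
    trajs = {}
    for strategy in StrategyKind:
        spec = SimulationSpec(strategy=strategy, params=default_params,
                              output_step=2.0)
        trajs[strategy] = run_simulation(spec)
    return trajs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210411)
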