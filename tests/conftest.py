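import numpy as np
import pytest

from synaptrap.config import RunConfig
from synaptrap.polymer import DsParams, SsParams, ThermalContext, tether_states
from synaptrap.simulate import SimulationConfig, simulate_dataset
from synaptrap.workflow import run_analyze

CLOSURE_SEED = 42
CLOSURE_N_CYCLES = 200


@pytest.fixture(scope="session")
def thermal():
    return ThermalContext()


@pytest.fixture(scope="session")
def handle_params():
    """Default dsDNA handle pair: 2 x 2.5 kbp at 0.34 nm/bp."""
    return DsParams(contour_length=1700.0, persistence_length=45.0,
                    stretch_modulus=1200.0)


@pytest.fixture(scope="session")
def ss100():
    return SsParams(contour_length=100.0, persistence_length=2.0)


@pytest.fixture(scope="session")
def states():
    return tether_states()


@pytest.fixture(scope="session")
def closure_run():
    """One 200-cycle generator -> pipeline round trip shared by the
    pipeline-invariant and acceptance tests (the expensive fixture)."""
    sim = SimulationConfig(seed=CLOSURE_SEED)
    trace, truth = simulate_dataset(sim, CLOSURE_N_CYCLES)
    result = run_analyze(RunConfig(), [trace])
    merged = result.cycles.merge(truth, on="cycle_id",
                                 suffixes=("_pred", "_true"))
    return {"sim": sim, "truth": truth, "result": result, "merged": merged}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
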