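import numpy as np
import pytest

from bubblerelax import (BubbleSpec, ChainState, IntegratorConfig, ModelParameters,
                         initial_state, thermalise)
from bubblerelax.synthetic import mini_ensemble


@pytest.fixture(scope="session")
def at_params() -> ModelParameters:
    return ModelParameters.at()


@pytest.fixture(scope="session")
def gc_params() -> ModelParameters:
    return ModelParameters.gc()


@pytest.fixture(scope="session")
def cfg() -> IntegratorConfig:
    return IntegratorConfig()


@pytest.fixture(scope="session")
def random_states(at_params):
    """Mildly displaced random chain states for identity/gradient checks."""
    rng = np.random.default_rng(12345)
    return [ChainState(rng.normal(0.0, 0.4, 24), rng.normal(0.0, 2.0, 24))
            for _ in range(25)]


@pytest.fixture(scope="session")
def thermal_at_state(at_params, cfg) -> ChainState:
    """One N=300 AT chain thermalised briefly at 0.043 eV per site."""
    state = initial_state(300, 0.043, seed=2024, mass=at_params)
    return thermalise(state, at_params, cfg, duration=0.2, check_temperature=False)


@pytest.fixture(scope="session")
def at_mini_ensemble(at_params):
    """Eight short AT realisations of a w=11, h=5 bubble (shared fixture)."""
    return mini_ensemble(at_params, BubbleSpec(h=5.0, w=11), n_runs=8, seed=77,
                         short_ns=1.0, therm_ns=0.3)
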