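import pytest

from seedswitch import ModelParameters, SimulationSettings


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def monostable_params() -> ModelParameters:
    """Low-variability parameterization: monostable after the GA rise."""
    return ModelParameters(theta_I_ABA=7.0)


@pytest.fixture(scope="session")
def bistable_params() -> ModelParameters:
    """High-variability parameterization: bistable after the GA rise."""
    return ModelParameters(theta_I_ABA=5.8)


@pytest.fixture(scope="session")
def linear_params() -> ModelParameters:
    """All regulatory coefficients effectively removed (tiny C values break
    every Hill feedback to machine precision; C must stay > 0 by contract)."""
    eps = 1e-300
    return ModelParameters(C_ABA_I=eps, C_GA_I=eps, C_I_ABA=eps, C_I_GA=eps)


@pytest.fixture
def fast_settings() -> SimulationSettings:
    return SimulationSettings(n_seeds=50, t_final=300.0, rng_seed=42)
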