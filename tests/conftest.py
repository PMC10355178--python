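import numpy as np
import pytest

from defsym import ModelParameters, ResidentTraits, SimulationSettings


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default parameter set."""
    return ModelParameters()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230505)


@pytest.fixture()
def fast_settings() -> SimulationSettings:
    """Small simulation settings for structural tests."""
    return SimulationSettings(T_evo=20, T_eco=20.0, seed=7)


def random_traits(rng: np.random.Generator) -> ResidentTraits:
    return ResidentTraits(y=float(rng.uniform(0, 1)),
                          beta_P=float(rng.uniform(0.5, 4.0)))
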