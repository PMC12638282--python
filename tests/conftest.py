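import numpy as np
import pytest

from flash_esd import (
    ESDParameters,
    ModelVariant,
    SuiteSpec,
    generate_profile_suite,
)


@pytest.fixture(scope="session")
def esd1_rrs1() -> ModelVariant:
    return ModelVariant("ESD1", "RRS1")


@pytest.fixture(scope="session")
def best_params() -> ESDParameters:
    """Best-fit parameter set for the step-response depletion model."""
    return ESDParameters(g=0.22, r=0.29, smin=0.65)


@pytest.fixture(scope="session")
def default_suite():
    """The 52-profile synthetic delivery suite used across tests (seed 1)."""
    return generate_profile_suite(SuiteSpec(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
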