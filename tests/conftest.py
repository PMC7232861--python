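import numpy as np
import pytest

from smcpk.params import (
    PopulationParameters,
    Subject,
    VariabilityParameters,
    default_parameters,
)
from smcpk.pk import individual_parameters


@pytest.fixture(scope="session")
def pop() -> PopulationParameters:
    return default_parameters()[0]


@pytest.fixture(scope="session")
def var() -> VariabilityParameters:
    return default_parameters()[1]


@pytest.fixture(scope="session")
def var0(var) -> VariabilityParameters:
    """No IIV, no residual error."""
    return var.with_no_variability()


@pytest.fixture(scope="session")
def typical_subject() -> Subject:
    return Subject(id="typical", age_months=36.0, weight_kg=11.5)


@pytest.fixture(scope="session")
def typical_ind(pop, typical_subject):
    return individual_parameters(pop, typical_subject)


@pytest.fixture(scope="session")
def reference_ind(pop):
    """10-kg child with (effectively) full enzyme maturation."""
    return individual_parameters(pop, Subject("ref", 1e9, 10.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(12345))
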