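import pytest

from odtcea.parameters import (
    morocco_2022_parameters,
    reference_annual_outcomes,
    reference_base_case,
)


@pytest.fixture(scope="session")
def params():
    """The built-in Moroccan 2022 reference parameter set."""
    return morocco_2022_parameters()


@pytest.fixture(scope="session")
def annual_targets():
    """Published annual outcome percentages per drug group."""
    return reference_annual_outcomes()


@pytest.fixture(scope="session")
def base_case():
    """Published base-case (cost, QALY) per arm and per group."""
    return reference_base_case()


@pytest.fixture()
def fresh_params(params):
    """A mutable copy of the reference set for tests that perturb it."""
    return params.copy()
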