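import pytest

from gtaudit.simulate import (
    LinePlan,
    SimParams,
    default_line_plans,
    generate_reference,
)


@pytest.fixture(scope="session")
def params() -> SimParams:
    return SimParams(seed=11)


@pytest.fixture(scope="session")
def small_reference(params):
    """A 60 kb host with 8 gene models, vector and foreign panel."""
    return generate_reference(params, l_host=60_000, n_genes=8)


@pytest.fixture(scope="session")
def plans() -> list[LinePlan]:
    return default_line_plans(insertion_site=30_000)
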