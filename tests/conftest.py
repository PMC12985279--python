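import pytest

from triagecea import UnitCostTable, builtin_strategies, fixture_cohort


@pytest.fixture(scope="session")
def cohort130():
    """The canonical deterministic 130-patient reference cohort."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def unit_costs():
    return UnitCostTable()


@pytest.fixture(scope="session")
def strategies():
    return {s.name: s for s in builtin_strategies()}
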