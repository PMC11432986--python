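import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

from sedror import (  # noqa: E402
    SimConfig,
    GroupSpec,
    fixture_from_tables,
    primary_term_set,
    simulate,
)
from sedror.selection import ExposureGroup  # noqa: E402


@pytest.fixture(scope="session")
def fixture_ds():
    return fixture_from_tables()


@pytest.fixture(scope="session")
def primary_ts():
    return primary_term_set()


@pytest.fixture(scope="session")
def small_sim():
    """100-report single-group synthetic dataset with its truth ledger."""
    cfg = SimConfig(
        groups=[GroupSpec(ExposureGroup.DEX, 100, 0.1, 3.0)], seed=42
    )
    return simulate(cfg)
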