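import pytest
from hypothesis import HealthCheck, settings

from retrodose import Patient, Regimen, SimulationSettings, generate_fixture_spec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def adult() -> Patient:
    return Patient(age=40, weight=70, height=180)


@pytest.fixture(scope="session")
def regimen() -> Regimen:
    return Regimen(dose=300.0, interval=12.0)


@pytest.fixture(scope="session")
def medium_spec():
    """Mid-range elimination fixture with covariate relations."""
    return generate_fixture_spec("with_covariates", 1)


@pytest.fixture(scope="session")
def slow_spec():
    return generate_fixture_spec("slow_clearance", 1)


@pytest.fixture(scope="session")
def fast_spec():
    return generate_fixture_spec("fast_clearance", 1)


@pytest.fixture
def small_settings() -> SimulationSettings:
    """Reduced Monte Carlo size for quick unit tests."""
    return SimulationSettings(n_virtual=4000, seed=11)
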