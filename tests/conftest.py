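import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import n2opools as n

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def vessel_3c() -> n.VesselConfig:
    return n.VesselConfig.from_treatment("3c-test", "3c")


@pytest.fixture(scope="session")
def clean_scenario() -> n.SyntheticScenario:
    """Noise-free scenario: observables equal the generating truth."""
    return n.SyntheticScenario(seed=11, noise_flux_rel=0.0,
                               noise_delta_permil=0.0, noise_at_percent=0.0)


@pytest.fixture(scope="session")
def clean_experiment(clean_scenario) -> n.SyntheticExperiment:
    return n.generate_experiment(clean_scenario)


@pytest.fixture(scope="session")
def noisy_experiment() -> n.SyntheticExperiment:
    return n.generate_experiment(n.SyntheticScenario(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
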