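import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Deterministic desk-scale study conditions: no sensor or trait noise."""
    from tomaqual.simulate import SimScenario

    return SimScenario(
        days=40,
        stagger_days=10,
        n_plants=12,
        temp_noise_sigma=0.0,
        humidity_noise_sigma=0.0,
        radiation_noise_sigma=0.0,
        missing_rate=0.0,
        trait_noise_scale=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_scenario):
    from tomaqual.simulate import simulate_study

    return simulate_study(noiseless_scenario)
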