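import pytest
from hypothesis import HealthCheck, settings

import oralbiofilm as ob

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def donor1_chx():
    return ob.load_parameters("recovery/donor1/CHX")


@pytest.fixture(scope="session")
def donor1_naocl():
    return ob.load_parameters("recovery/donor1/NaOCl")


@pytest.fixture(scope="session")
def donor2_chx():
    return ob.load_parameters("recovery/donor2/CHX")


@pytest.fixture(scope="session")
def aged_chx():
    return ob.load_parameters("aged/CHX")


@pytest.fixture(scope="session")
def all_recovery_params():
    return {
        f"{donor}/{agent}": ob.load_parameters(f"recovery/{donor}/{agent}")
        for donor in ("donor1", "donor2")
        for agent in ("CHX", "IPI", "NaOCl")
    }


@pytest.fixture(scope="session")
def recovery_results(all_recovery_params):
    """The full six-group recovery study at default tolerances."""
    return ob.run_recovery_study(all_recovery_params)


@pytest.fixture(scope="session")
def fast_protocol():
    """Calibration-grade protocol: slightly relaxed solver tolerances."""
    return ob.ProtocolSpec(rtol=1e-6, atol=1e-10)
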