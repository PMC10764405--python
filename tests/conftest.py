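import pytest
from hypothesis import HealthCheck, settings

import phyllofield as pf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def costoid_result() -> pf.SimulationResult:
    """Fig. 2c lower-left (costoid) run to 30 primordia."""
    preset = pf.get_preset("fig2c_costoid")
    return pf.run(preset.params, pf.SimulationConfig(max_primordia=30))


@pytest.fixture(scope="session")
def fibonacci_result() -> pf.SimulationResult:
    """Fig. 2c upper-right (Fibonacci spiral) run to 100 primordia."""
    preset = pf.get_preset("fig2c_fibonacci")
    return pf.run(preset.params, pf.SimulationConfig(max_primordia=100))


@pytest.fixture(scope="session")
def enlargement_result() -> pf.SimulationResult:
    """Fig. 4f run with the SAM-enlargement schedule."""
    preset = pf.get_preset("fig4f_enlargement")
    return pf.run(preset.params, pf.SimulationConfig(max_primordia=30), preset.schedule)
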