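import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from glycotraits.simulate import SimulationDesign, make_profile, simulate_spectrum


@pytest.fixture(scope="session")
def ntc_profile():
    return make_profile("ntc_like")


@pytest.fixture(scope="session")
def knockdown_profile():
    return make_profile("knockdown_like")


@pytest.fixture(scope="session")
def small_design():
    """Narrow acquisition window covering every preset species; fast to grid."""
    return SimulationDesign(mz_range=(1040.0, 3300.0))


@pytest.fixture(scope="session")
def clean_design():
    """Noise-free, drift-free design for exact-recovery checks."""
    return SimulationDesign(
        mz_range=(1040.0, 3300.0),
        noise_sigma=0.0,
        baseline_level=0.0,
        replicate_sigma=0.0,
    )


@pytest.fixture(scope="session")
def clean_spectrum(ntc_profile, clean_design):
    return simulate_spectrum(ntc_profile, clean_design, 0, 0, master_seed=11)
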