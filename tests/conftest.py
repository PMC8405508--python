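import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from aggpk import Design, PopulationParams, get_model

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CASE2_TIMES = np.array([0.1, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0])


@pytest.fixture(scope="session")
def case2_model():
    return get_model("twocomp_oral")


@pytest.fixture(scope="session")
def case2_params():
    return PopulationParams(
        beta=[5.0, 10.0, 30.0, 10.0, 1.0], omega=np.eye(5) * 0.09, sigma_add2=0.04
    )


@pytest.fixture
def case2_design():
    def make(n_subjects=100):
        return Design(times=CASE2_TIMES, dose_amount=100.0, n_subjects=n_subjects)

    return make


@pytest.fixture(scope="session")
def wang_model():
    return get_model("wang")


@pytest.fixture(scope="session")
def wang_params():
    return PopulationParams(beta=[0.5], omega=[[0.04]], sigma_add2=0.1)


@pytest.fixture(scope="session")
def transit_model():
    return get_model("transit2")


@pytest.fixture(scope="session")
def transit_params():
    return PopulationParams(
        beta=[1.0, 5.0, 10.0, 30.0, 10.0], omega=np.eye(5) * 0.09, sigma_add2=0.04
    )
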