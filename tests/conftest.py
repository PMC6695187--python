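import dataclasses

import numpy as np
import pytest

import apldyn as a

# Warm the compiled objective once so individual tests don't pay JIT cost.
from apldyn._fastsim import fast_observe  # noqa: E402


@pytest.fixture(scope="session", autouse=True)
def _warm_fastsim():
    p, b3, g = a.patient_parameters("18")
    fast_observe(p, a.ical_protocol(b3, g), (1000.0, 1000.0), np.arange(5.0))


@pytest.fixture(scope="session")
def p18():
    params, beta3, gamma = a.patient_parameters("18")
    return params, beta3, gamma


@pytest.fixture(scope="session")
def p22():
    params, beta3, gamma = a.patient_parameters("22")
    return params, beta3, gamma


@pytest.fixture(scope="session")
def fixed():
    return a.fixed_parameters()


@pytest.fixture
def scenario2_params():
    """A bistable parameter set (leukemia-free and disease attractors coexist)."""
    return a.ModelParameters(
        r_N=2880.0, mu_N=2.88, r_A=3.8808, K_A=25000.0, mu_A=0.6648,
        beta1=0.001, beta2=0.004,
    )


@pytest.fixture
def scenario3_params(scenario2_params):
    """Leukemia develops from any positive initial state."""
    return dataclasses.replace(scenario2_params, beta2=0.001)


@pytest.fixture
def scenario1_params(scenario2_params):
    """Leukemia is cleared from any initial state."""
    return dataclasses.replace(scenario2_params, beta1=1e-5)


@pytest.fixture
def atra_only(fixed):
    """An ATRA-only schedule (no chemotherapy doses)."""
    return dataclasses.replace(a.ical_protocol(0.3, 0.0), dose_days=(),
                               label="ATRA-only")
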