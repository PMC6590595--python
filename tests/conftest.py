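import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pathlin import make_toy_model, simulate_to_steady_state

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def decay1():
    return make_toy_model("decay1")


@pytest.fixture(scope="session")
def bind2():
    return make_toy_model("bind2")


@pytest.fixture(scope="session")
def chain3():
    return make_toy_model("chain3")


@pytest.fixture(scope="session")
def affine8():
    return make_toy_model("affine_n", n=8)


@pytest.fixture(scope="session")
def bind2_ss(bind2):
    """bind2 steady state at the reference base input (2, 2)."""
    return simulate_to_steady_state(bind2, np.array([2.0, 2.0]))
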