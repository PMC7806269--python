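import numpy as np
import pytest

from avlearn import sequences
from avlearn.observers import ObserverParams


@pytest.fixture(scope="session")
def session20():
    """Short sinusoidal session with 20-dot clouds."""
    return sequences.make_session("sinusoid", duration=240.0, n_dots=20, seed=11)


@pytest.fixture(scope="session")
def session5():
    """Short sinusoidal session with moment-matched 5-dot clouds."""
    return sequences.make_session(
        "sinusoid", duration=240.0, n_dots=5, seed=12, exact_moments=True
    )


@pytest.fixture(scope="session")
def params_bayes():
    return ObserverParams(sigma_a=6.0, p_common=0.7, sigma_0=12.0, kappa=15.0)


@pytest.fixture(scope="session")
def params_exp():
    return ObserverParams(sigma_a=6.0, p_common=0.7, sigma_0=12.0, gamma=0.6)


@pytest.fixture(scope="session")
def params_inst():
    return ObserverParams(sigma_a=6.0, p_common=0.7, sigma_0=12.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
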