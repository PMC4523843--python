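import numpy as np
import pytest

from rfmflow import RateProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_profile(rng, n, low=0.1, high=10.0) -> RateProfile:
    """Log-uniform random rate profile, the stock test instance."""
    return RateProfile(np.exp(rng.uniform(np.log(low), np.log(high), n + 1)))


def flux_vector(profile: RateProfile, e: np.ndarray) -> np.ndarray:
    """All n+1 steady-state flux expressions; they must agree at equilibrium."""
    lam = profile.rates
    return np.concatenate((
        [lam[0] * (1.0 - e[0])],
        lam[1:-1] * e[:-1] * (1.0 - e[1:]),
        [lam[-1] * e[-1]],
    ))
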