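import numpy as np
import pytest
from hypothesis import settings

from desyn.countio import CountMatrix

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cm():
    """6 genes x 4 samples, two per group, plain integers."""
    counts = np.array([
        [10, 12, 11, 13],
        [100, 90, 110, 95],
        [0, 1, 0, 2],
        [55, 60, 58, 61],
        [7, 8, 6, 9],
        [300, 310, 290, 305],
    ], dtype=float)
    return CountMatrix(counts, [f"g{i}" for i in range(6)],
                       ["s1", "s2", "s3", "s4"], np.array([1, 1, 2, 2]))


def nb_counts(rng, mu, phi, size):
    """NB(mu, phi) draws in the variance = mu + phi*mu^2 parameterization."""
    if np.isscalar(phi) and phi <= 0:
        return rng.poisson(mu, size=size).astype(float)
    r = 1.0 / np.asarray(phi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return rng.negative_binomial(r, r / (r + mu), size=size).astype(float)
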