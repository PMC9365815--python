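import numpy as np
import pytest

from wpwlpt.synthetic import (
    default_circles_spec,
    default_squares_spec,
    make_circles,
    make_squares,
)


@pytest.fixture(scope="session")
def circles_pair():
    """Default noisy circles benchmark image (overlapping-mode histogram)."""
    return make_circles(default_circles_spec(noise_sigma=30.0, seed=0))


@pytest.fixture(scope="session")
def squares_pair():
    """Default noisy squares benchmark image."""
    return make_squares(default_squares_spec(noise_sigma=50.0, seed=0))


@pytest.fixture(scope="session")
def clean_circles_pair():
    return make_circles(default_circles_spec(noise_sigma=0.0, seed=0))


@pytest.fixture(scope="session")
def clean_squares_pair():
    return make_squares(default_squares_spec(noise_sigma=0.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
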