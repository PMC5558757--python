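import numpy as np
import pytest

from polyasig.synthetic import default_profiles, generate_dataset


@pytest.fixture(scope="session")
def strong_dataset():
    """Small strongly-separable synthetic dataset (120 true + 120 pseudo)."""
    return generate_dataset(default_profiles("strong", 1.0), 120, 120, seed=3)


@pytest.fixture(scope="session")
def null_dataset():
    """Signal-free dataset: both classes drawn from identical distributions."""
    return generate_dataset(default_profiles("strong", 0.0), 120, 120, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_window(rng, variant="AATAAA"):
    """A random valid 206-nt window with the hexamer planted at 100-105."""
    flank = lambda: "".join(rng.choice(list("ACGT"), size=100))
    return flank() + variant + flank()


@pytest.fixture()
def make_window(rng):
    return lambda variant="AATAAA": random_window(rng, variant)
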