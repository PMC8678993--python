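import numpy as np
import pytest

from hippospec.synthetic import PhantomConfig

#: Pixel minima scaled to the small test geometry (the full-study minima of
#: 120/150/300/300 are exercised against the default geometry separately).
SMALL_MINIMA = {"GR": 10, "PY": 10, "MU": 10, "MO": 10}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """A small, fast phantom geometry for unit tests."""
    return PhantomConfig(shape=(24, 26), seed=7)


@pytest.fixture
def clean_config():
    """Small geometry with every stochastic ingredient switched off."""
    return PhantomConfig(
        shape=(24, 26),
        noise_sigma=0.0,
        drift_scale=0.0,
        animal_sigma=0.0,
        thickness_sigma=0.0,
        seed=7,
    )
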