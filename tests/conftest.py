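import numpy as np
import pytest

from skitrace.simulate import SkierSpec, default_course, simulate_race
from skitrace.subtechnique import default_training_set


@pytest.fixture(scope="session")
def training_set():
    return default_training_set(seed=42, windows_per_class=60)


@pytest.fixture(scope="session")
def race_sim():
    """One default-noise 4-lap race on the built-in course, fixed seed."""
    return simulate_race(default_course(), SkierSpec(), n_laps=4, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
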