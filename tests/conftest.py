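import numpy as np
import pytest
from hypothesis import settings

from dastride.spiketrain import SpikeTrain

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def poisson_train(rate, duration, rng):
    """Homogeneous Poisson spike train (sorted uniform arrival times)."""
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0, duration, size=n))
    t = np.unique(t)
    return SpikeTrain(t, duration)


def random_train(rng, n_max=200, duration=60.0):
    """Random train with a mix of short and long ISIs (burst-rich)."""
    n = int(rng.integers(2, n_max))
    isis = np.where(rng.random(n) < 0.4,
                    rng.uniform(0.005, 0.2, size=n),
                    rng.uniform(0.2, 1.5, size=n))
    t = np.cumsum(isis)
    t = t[t < duration]
    if t.size < 2:
        t = np.array([0.1, 0.5])
    return SpikeTrain(t, duration)
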