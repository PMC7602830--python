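import numpy as np
import pytest

from varivent import CPMParameters, synth_lung_phantom
from varivent.oscillometry import DEFAULT_FREQUENCIES_HZ


@pytest.fixture(scope="session")
def frequencies():
    return np.array(DEFAULT_FREQUENCIES_HZ)


@pytest.fixture(scope="session")
def rabbit_cpm():
    """Plausible constant-phase parameters for a healthy rabbit pup."""
    return CPMParameters(raw=20.0, iaw=0.1, g=400.0, h=2000.0)


@pytest.fixture(scope="session")
def small_phantom():
    return synth_lung_phantom(
        shape=(24, 24, 24),
        zone_fractions=(0.5, 0.3, 0.2),
        zone_uptake_means=(2.0, 1.0, 0.5),
        seed=11,
    )
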