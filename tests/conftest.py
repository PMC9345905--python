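import numpy as np
import pytest

from precigrip import build_parametric_hand, load_muscle_table, sensing_device
from precigrip.muscles import DEFAULT_STRENGTH_SCALE


@pytest.fixture(scope="session")
def muscle_set():
    """Muscle table with the tabulated (unscaled) maxima."""
    return load_muscle_table()


@pytest.fixture(scope="session")
def muscle_set_scaled():
    """Muscle table with mechanically realistic maxima, as used by the synthesis pipeline."""
    return load_muscle_table(strength_scale=DEFAULT_STRENGTH_SCALE)


@pytest.fixture(scope="session")
def hand():
    return build_parametric_hand()


@pytest.fixture(scope="session")
def device():
    return sensing_device()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
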