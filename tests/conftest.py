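import numpy as np
import pytest

from eistrack import (
    ArrayType,
    ExtendedParams,
    RandlesParams,
    SessionMeta,
    SessionTime,
    default_grid,
    simulate_spectrum,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def irox_meta():
    return SessionMeta("arr01", 1, ArrayType.IROX, SessionTime.in_vitro())


@pytest.fixture
def pt_meta():
    return SessionMeta("arr02", 1, ArrayType.PT, SessionTime.in_vitro())


@pytest.fixture
def hockey_stick_vivo_params():
    """Published in-vivo hockey-stick fitted means (Q in rad/s convention)."""
    return RandlesParams(R_E=6.2e10, Q=30e-8 / (2 * np.pi) ** 0.64, n=0.64, R_S=138e3)


@pytest.fixture
def randles_spectrum(grid, irox_meta, hockey_stick_vivo_params):
    return simulate_spectrum(
        ExtendedParams.randles(hockey_stick_vivo_params), grid, irox_meta
    )
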