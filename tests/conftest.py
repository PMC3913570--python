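import numpy as np
import pytest

from dscaif import (
    AcquisitionParams,
    AifModelParams,
    build_phantom,
    make_grid,
    signal_matrix_to_concentration,
    true_aif_curve,
)

DEFAULT_PHANTOM_SEED = 0


@pytest.fixture(scope="session")
def aif_params():
    return AifModelParams()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def coarse_grid(acq):
    """Default 1 s grid over 90 s, aligned with the arrival time."""
    return acq.grid()


@pytest.fixture(scope="session")
def fine_grid():
    """0.01 s grid over 90 s for interpolated shape statistics."""
    return make_grid(90.0, 0.01)


@pytest.fixture(scope="session")
def true_aif(coarse_grid, aif_params):
    return true_aif_curve(coarse_grid, aif_params)


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom(seed=DEFAULT_PHANTOM_SEED)


@pytest.fixture(scope="session")
def default_phantom_conc(default_phantom):
    ds = default_phantom
    return signal_matrix_to_concentration(ds.curves, ds.acq.s0, ds.acq)


def brute_force_convolution(a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """O(n^2) double-loop discrete convolution oracle (rectangle rule)."""
    n = len(a)
    out = np.zeros(n)
    for i in range(n):
        for j in range(i + 1):
            out[i] += a[j] * b[i - j]
    return out * dt
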