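import numpy as np
import pandas as pd
import pytest

from fmtheta.epochs import EpochSet
from fmtheta.forward import build_grid, compute_leadfield, helmet_geometry


@pytest.fixture(scope="session")
def geometry():
    """Small helmet used across forward/beamformer tests."""
    return helmet_geometry(n_channels=32)


@pytest.fixture(scope="session")
def grid(geometry):
    return build_grid(geometry, spacing_mm=24.0)


@pytest.fixture(scope="session")
def leadfield(geometry, grid):
    return compute_leadfield(grid, geometry)


def make_epochs(
    data: np.ndarray,
    sfreq: float = 100.0,
    tmin: float = -1.5,
    conditions=None,
    correct=None,
    rt_ms=None,
) -> EpochSet:
    """EpochSet around a raw array with simple defaults for the metadata."""
    n = data.shape[0]
    conditions = ["Go"] * n if conditions is None else list(conditions)
    correct = [True] * n if correct is None else list(correct)
    rt_ms = [400.0] * n if rt_ms is None else list(rt_ms)
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "correct": correct,
            "rt_ms": rt_ms,
            "onset_s": np.arange(n, dtype=float),
        }
    )
    return EpochSet(data=data, sfreq=sfreq, tmin=tmin, trial_meta=meta)


@pytest.fixture
def make_epochs_fn():
    return make_epochs
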