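import logging

import numpy as np
import pytest

from spbfret import SimConfig, get_fixture, simulate_fret_image_set


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    """Keep expected per-cell warnings out of the test output."""
    logging.getLogger("spbfret").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A small, fast image-set configuration for unit tests."""
    return SimConfig(apparent_efficiency_pct=14.0, n_cells_DA=6, n_cells_D=6,
                     n_cells_bg=4, image_shape_px=(48, 48), seed=42)


@pytest.fixture(scope="session")
def tiny_noiseless_set(tiny_config):
    return simulate_fret_image_set(tiny_config.noiseless())


def brute_force_quartiles(values, q):
    """Inclusive linear-interpolation quantile, written out by hand."""
    x = sorted(float(v) for v in values)
    pos = (len(x) - 1) * q
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return x[lo] + (pos - lo) * (x[hi] - x[lo])
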