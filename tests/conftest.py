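import numpy as np
import pytest

from swayscale import Series1D, bin_loglog


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def overall_slope(plot) -> float:
    """OLS slope over all binned points of a log-log plot."""
    b = bin_loglog(plot)
    return float(np.polyfit(b.x, b.y, 1)[0])


def position(values, dt=1.0) -> Series1D:
    return Series1D(np.asarray(values, dtype=float), dt=dt, label="position")


def velocity(values, dt=1.0) -> Series1D:
    return Series1D(np.asarray(values, dtype=float), dt=dt, label="velocity")
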