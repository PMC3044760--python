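"""Stabilogram diffusion analysis (SDA).

SDA measures how far the center of pressure wanders as a function of the
observation interval: the mean squared displacement <(dx)^2> over all
pairs of samples separated by a lag dt, plotted against dt in log-log
coordinates (the *diffusion plot*).  For a fractional Brownian motion the
slope is 2H; slope 1 (ordinary Brownian motion) is the boundary between
persistent (>1) and anti-persistent (<1) increments.  Because SDA does
not integrate its input, a cross-over in the diffusion plot of a position
series reveals bounding of the *differenced* series — the velocity.
"""

from __future__ import annotations

import warnings

import numpy as np

from .scaling import LogLogPlot
from .series import Series1D, require_label

__all__ = ["sda_msd", "default_max_lag"]


def default_max_lag(n: int) -> int:
    """Largest lag keeping three non-overlapping intervals: floor(n/3).

    For a 1024-point recording this gives 341, i.e. lags of 25 ms up to
    8525 ms at 40 Hz.
    """
    return n // 3


def sda_msd(s: Series1D, max_lag: int | None = None) -> LogLogPlot:
    """Mean squared displacement versus lag, on log-log axes.

    For each lag dt in 1..max_lag the ordinate is the mean of
    (x[t+dt] - x[t])^2 over all overlapping pairs; the abscissa is the
    lag in milliseconds.  Lags with exactly zero mean squared
    displacement (possible only for degenerate input) are dropped with a
    warning since their logarithm is undefined.
    """
    require_label(s, "position", "sda_msd")
    n = len(s)
    if max_lag is None:
        max_lag = default_max_lag(n)
    if not (1 <= max_lag <= n // 3):
        raise ValueError(
            f"max_lag must lie in [1, n//3] = [1, {n // 3}], got {max_lag}"
        )
    x = s.values
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for i, lag in enumerate(lags):
        d = x[lag:] - x[:-lag]
        msd[i] = np.mean(d * d)
    keep = msd > 0.0
    if not np.all(keep):
        warnings.warn(
            f"sda_msd: dropped {np.count_nonzero(~keep)} lag(s) with zero "
            "mean squared displacement",
            stacklevel=2,
        )
    lags_ms = lags[keep] * s.dt * 1000.0
    return LogLogPlot(
        log_x=np.log10(lags_ms),
        log_y=np.log10(msd[keep]),
        abscissa_role="lag_ms",
        source="SDA",
    )
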