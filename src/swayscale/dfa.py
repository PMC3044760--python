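"""Detrended fluctuation analysis (DFA).

The series is first integrated into the profile X(k) — the accumulated
departure from the global mean — then split into non-overlapping windows
of length n; a least-squares line is fitted and subtracted in each
window, and F(n) is the root-mean-square of the residuals pooled over
all retained points.  On log-log axes the slope of F(n) versus n is H
for a stationary (fGn-like) input and H+1 for a diffusive (fBm-like)
one, making 0.5 the persistence boundary: slopes above 0.5 indicate
persistent correlations in the analyzed series itself (the built-in
integration means DFA, unlike SDA, probes the series it is given).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .scaling import LogLogPlot
from .series import Series1D

__all__ = ["dfa_profile", "dfa_fluctuation", "FluctuationPlot"]

DEFAULT_N_MIN = 10
DEFAULT_N_MAX = 512
DEFAULT_GRID_SIZE = 40


@dataclass(frozen=True)
class FluctuationPlot:
    """Raw (n, F(n)) pairs plus their log-log plot."""

    n: np.ndarray
    F: np.ndarray
    loglog: LogLogPlot


def dfa_profile(s: Series1D) -> Series1D:
    """Integrated profile X(k) = sum_{i<=k} (x_i - mean(x)).

    Same length as the input; the final value is zero by construction.
    """
    x = s.values
    return s.with_values(np.cumsum(x - x.mean()), label="profile")


def window_grid(n_min: int, n_max: int, size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """~`size` log-spaced integer window lengths in [n_min, n_max].

    Duplicates after rounding are removed.  Denser grids gain nothing
    once the plot is binned at 0.1-decade resolution.
    """
    g = np.unique(
        np.round(np.geomspace(n_min, n_max, size)).astype(int)
    )
    return g[(g >= n_min) & (g <= n_max)]


def _fluct_one(profile: np.ndarray, n: int) -> float:
    """RMS residual of per-window linear detrending at window length n."""
    nw = profile.size // n
    seg = profile[: nw * n].reshape(nw, n)
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    denom = np.dot(t_c, t_c)
    means = seg.mean(axis=1, keepdims=True)
    slopes = (seg @ t_c)[:, None] / denom
    resid = seg - means - slopes * t_c
    return float(np.sqrt(np.mean(resid * resid)))


def dfa_fluctuation(
    s: Series1D,
    n_min: int = DEFAULT_N_MIN,
    n_max: int = DEFAULT_N_MAX,
    n_grid: np.ndarray | int | None = None,
) -> FluctuationPlot:
    """Fluctuation function F(n) over a grid of window lengths.

    Windows partition the profile from the start; samples beyond
    floor(N/n)*n are discarded.  Detrending is first-order (a straight
    line per window).  F(n) = 0 (constant input) is dropped with a
    warning since its logarithm is undefined.
    """
    N = len(s)
    if not (4 <= n_min < n_max <= N // 2):
        raise ValueError(
            f"need 4 <= n_min < n_max <= N/2 = {N // 2}; got ({n_min}, {n_max})"
        )
    if n_grid is None:
        grid = window_grid(n_min, n_max)
    elif np.isscalar(n_grid):
        grid = window_grid(n_min, n_max, int(n_grid))
    else:
        grid = np.unique(np.asarray(n_grid, dtype=int))
        if grid[0] < n_min or grid[-1] > n_max:
            raise ValueError("explicit n_grid must lie within [n_min, n_max]")
    profile = dfa_profile(s).values
    F = np.array([_fluct_one(profile, int(n)) for n in grid], dtype=float)
    keep = F > 0.0
    if not np.all(keep):
        warnings.warn(
            f"dfa_fluctuation: dropped {np.count_nonzero(~keep)} window "
            "length(s) with F(n) = 0",
            stacklevel=2,
        )
    loglog = LogLogPlot(
        log_x=np.log10(grid[keep].astype(float)),
        log_y=np.log10(F[keep]),
        abscissa_role="interval_length",
        source="DFA",
    )
    return FluctuationPlot(n=grid[keep], F=F[keep], loglog=loglog)
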