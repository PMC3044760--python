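"""Average absolute maximal velocity (AAMV).

If sway velocity is bounded between symmetric limits, the typical
per-window extreme of the velocity series estimates that bound.  AAMV
partitions a velocity series into non-overlapping windows (long enough
to capture at least one maximum and one minimum, 2 s by default),
collects each window's maximum and minimum, and averages the absolute
values of all these extrema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import Series1D, require_label

__all__ = ["AamvResult", "compute_aamv"]

DEFAULT_WINDOW_S = 2.0


@dataclass(frozen=True)
class AamvResult:
    """AAMV value with the per-window extrema it was averaged from."""

    value: float
    window_length_s: float
    n_windows: int
    per_window_extrema: np.ndarray  # shape (n_windows, 2): (max, min)


def compute_aamv(v: Series1D, window_s: float = DEFAULT_WINDOW_S) -> AamvResult:
    """AAMV = mean |extremum| over non-overlapping windows.

    Windows tile the series from the start; the incomplete tail is
    discarded.  The window must hold at least 2 samples and the series at
    least one full window.
    """
    require_label(v, "velocity", "compute_aamv")
    w = int(round(window_s / v.dt))
    if w < 2:
        raise ValueError(
            f"window of {window_s} s holds only {w} sample(s) at dt={v.dt}; need >= 2"
        )
    n_windows = len(v) // w
    if n_windows < 1:
        raise ValueError(
            f"series of {len(v)} samples has no complete {w}-sample window"
        )
    seg = v.values[: n_windows * w].reshape(n_windows, w)
    extrema = np.stack([seg.max(axis=1), seg.min(axis=1)], axis=1)
    return AamvResult(
        value=float(np.mean(np.abs(extrema))),
        window_length_s=window_s,
        n_windows=n_windows,
        per_window_extrema=extrema,
    )
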