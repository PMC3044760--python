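"""Core 1-D signal container and elementary signal operations.

All analyses in this package operate on :class:`Series1D`: a uniformly
sampled, finite, real-valued signal with an explicit sampling interval and
a role label ("position" or "velocity").  The label lets downstream stages
refuse input of the wrong kind — stabilogram diffusion analysis, for
instance, is defined on position series only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "Series1D",
    "ScalingExponent",
    "differentiate",
    "integrate",
    "low_pass",
    "read_cop_csv",
    "write_cop_csv",
]


@dataclass(frozen=True)
class Series1D:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values
        The samples.  Units are mm for position series and mm per sample
        for per-sample velocity (model output is unitless).
    dt
        Sampling interval in seconds (must be positive).
    label
        Role of the series: typically ``"position"`` or ``"velocity"``.
    """

    values: np.ndarray
    dt: float
    label: str = "position"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("Series1D requires a 1-D array of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("Series1D samples must all be finite")
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ValueError(f"sampling interval must be positive, got {self.dt}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Record duration in seconds (n * dt)."""
        return len(self) * self.dt

    def with_values(self, values: np.ndarray, label: str | None = None) -> "Series1D":
        return replace(self, values=values, label=self.label if label is None else label)


@dataclass(frozen=True)
class ScalingExponent:
    """A Hurst exponent H together with the raw slope it was read from.

    DFA convention: for a stationary (fGn-like) series the fitted slope
    equals H directly; for a diffusive (fBm-like) series it equals H + 1.
    """

    H: float
    family: str  # "fGn" or "fBm"
    alpha: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.family not in ("fGn", "fBm"):
            raise ValueError(f"family must be 'fGn' or 'fBm', got {self.family!r}")
        if np.isnan(self.alpha):
            object.__setattr__(
                self, "alpha", self.H if self.family == "fGn" else self.H + 1.0
            )

    @classmethod
    def from_alpha(cls, alpha: float) -> "ScalingExponent":
        """Classify a fitted DFA slope into the fGn/fBm continuum."""
        if alpha <= 1.0:
            return cls(H=alpha, family="fGn", alpha=alpha)
        return cls(H=alpha - 1.0, family="fBm", alpha=alpha)


def differentiate(s: Series1D, per_second: bool = False) -> Series1D:
    """First-difference a position series into a velocity series.

    By default velocity is expressed in per-sample displacement (no
    division by dt), which keeps the values directly comparable with the
    unitless bounded-velocity model.  Set ``per_second=True`` to rescale
    to units per second.  Scaling slopes are invariant to this factor.
    """
    if len(s) < 2:
        raise ValueError("cannot differentiate a series of length < 2")
    d = np.diff(s.values)
    if per_second:
        d = d / s.dt
    return Series1D(d, dt=s.dt, label="velocity")


def integrate(s: Series1D, x0: float = 0.0) -> Series1D:
    """Cumulatively sum a velocity series into a position series.

    The initial value ``x0`` is prepended, so the output has length
    ``len(s) + 1`` and ``integrate(differentiate(x), x[0])`` reproduces
    ``x`` exactly.
    """
    if not np.isfinite(x0):
        raise ValueError(f"initial value must be finite, got {x0}")
    out = np.empty(len(s) + 1)
    out[0] = x0
    np.cumsum(s.values, out=out[1:])
    out[1:] += x0
    return Series1D(out, dt=s.dt, label="position")


def low_pass(s: Series1D, cutoff_hz: float, order: int = 4) -> Series1D:
    """Zero-phase Butterworth low-pass filter (forward-backward).

    Emulates the acquisition chain of a force platform whose output is
    low-pass filtered (typically at 8 Hz for a 40 Hz recording).  Applied
    only to synthetic data; empirical recordings are assumed pre-filtered.
    Velocity series obtained by differencing are never re-filtered.
    """
    nyq = 0.5 / s.dt
    if not (0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = _signal.butter(order, cutoff_hz, btype="low", fs=s.fs, output="sos")
    filtered = _signal.sosfiltfilt(sos, s.values)
    # the filter has unit DC gain; any residual mean shift is an edge
    # transient artifact, so restore the series mean exactly
    filtered += s.values.mean() - filtered.mean()
    return s.with_values(filtered)


def read_cop_csv(path, dt: float | None = None) -> dict[str, Series1D]:
    """Read a COP recording from CSV/TSV.

    Expected columns: optional ``time_s``, plus ``cop_ap_mm`` and/or
    ``cop_ml_mm``.  Returns a mapping from axis name ("AP", "ML") to a
    position :class:`Series1D`.  If ``time_s`` is present the sampling is
    validated as uniform within 1e-6 s jitter; otherwise ``dt`` must be
    given.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        steps = np.diff(t)
        if steps.size == 0:
            raise ValueError(f"{path}: need at least two samples")
        step = float(np.median(steps))
        if np.max(np.abs(steps - step)) > 1e-6:
            raise ValueError(f"{path}: non-uniform sampling (jitter > 1e-6 s)")
        if dt is not None and abs(dt - step) > 1e-6:
            raise ValueError(f"{path}: time_s implies dt={step}, caller gave {dt}")
        dt = step
    if dt is None:
        raise ValueError(f"{path}: no time_s column; a sampling interval is required")

    out: dict[str, Series1D] = {}
    for col, axis in (("cop_ap_mm", "AP"), ("cop_ml_mm", "ML")):
        if col in df.columns:
            out[axis] = Series1D(df[col].to_numpy(dtype=float), dt=dt, label="position")
    if not out:
        raise ValueError(f"{path}: no cop_ap_mm / cop_ml_mm columns found")
    return out


def write_cop_csv(path, series_by_axis: dict[str, Series1D]) -> None:
    """Write per-axis position series to CSV with a time_s column."""
    import pandas as pd

    axes = list(series_by_axis)
    n = len(series_by_axis[axes[0]])
    dt = series_by_axis[axes[0]].dt
    for axis in axes[1:]:
        if len(series_by_axis[axis]) != n or series_by_axis[axis].dt != dt:
            raise ValueError("all axes must share length and sampling interval")
    data = {"time_s": np.arange(n) * dt}
    name = {"AP": "cop_ap_mm", "ML": "cop_ml_mm"}
    for axis, s in series_by_axis.items():
        data[name.get(axis, axis.lower())] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def require_label(s: Series1D, label: str, op: str) -> None:
    """Raise if a series does not carry the role a stage expects."""
    if s.label != label:
        raise ValueError(
            f"{op} expects a {label!r} series, got label {s.label!r}; "
            "relabel explicitly if this is intentional"
        )
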