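"""Log-binning, two-region slope regression, boundary comparison,
cross-over classification, and one-sample t-tests.

All three scaling analyses (SDA, DFA, PSD) end in the same statistical
protocol: the raw log-log plot is binned into 0.1-decade intervals on the
abscissa (averaging the log-log coordinates within each bin, so that the
logarithmic crowding of raw points does not bias the fit), and separate
ordinary-least-squares lines are fitted to the first and last runs of
binned points, excluding the central zone where an inflection may sit.
Each region's slope is then compared with the method's boundary value
(1.0 for SDA, 0.5 for DFA, 0.0 for PSD) to decide persistence versus
anti-persistence, and a short-term-persistent / long-term-anti-persistent
pattern is classified as a cross-over — the signature of a bounded
variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "LogLogPlot",
    "BinnedPlot",
    "SlopePair",
    "CrossoverVerdict",
    "bin_loglog",
    "two_region_slopes",
    "classify_crossover",
    "one_sample_t",
    "BOUNDARIES",
    "DEFAULT_REGIONS",
]

#: Boundary slope separating persistent from anti-persistent behaviour.
BOUNDARIES = {"SDA": 1.0, "DFA": 0.5, "PSD": 0.0}

#: Default two-region bin ranges (1-indexed, inclusive) per method.
DEFAULT_REGIONS = {
    "SDA": ((1, 8), (17, 24)),
    "DFA": ((1, 6), (12, 18)),
    "PSD": ((1, 10), (14, 25)),
}

#: Width of the abscissa bins, in log10 units.
DEFAULT_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class LogLogPlot:
    """A set of (log10 abscissa, log10 ordinate) points from one analysis.

    ``abscissa_role`` is one of ``lag_ms``, ``interval_length``,
    ``frequency_hz``; ``source`` names the producing method.
    """

    log_x: np.ndarray
    log_y: np.ndarray
    abscissa_role: str
    source: str

    def __post_init__(self) -> None:
        x = np.asarray(self.log_x, dtype=float)
        y = np.asarray(self.log_y, dtype=float)
        object.__setattr__(self, "log_x", x)
        object.__setattr__(self, "log_y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("log_x and log_y must be 1-D arrays of equal length")
        if x.size and np.any(np.diff(x) <= 0):
            raise ValueError("abscissae must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("ordinates must be finite")

    def __len__(self) -> int:
        return int(self.log_x.size)


@dataclass(frozen=True)
class BinnedPlot:
    """Per-bin mean points of a LogLogPlot (0.1-decade abscissa bins).

    ``x`` and ``y`` hold one averaged (log10, log10) point per non-empty
    bin, in abscissa order; ``bin_indices`` the underlying bin numbers
    relative to the anchor; ``counts`` the raw points per bin.
    """

    x: np.ndarray
    y: np.ndarray
    bin_indices: np.ndarray
    counts: np.ndarray
    bin_width: float
    anchor: float
    source: str

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class SlopePair:
    """Short- and long-term fitted slopes with their bin regions.

    For SDA and DFA the first (small-abscissa) region is the short term.
    For PSD the abscissa is frequency, so the roles invert: the first
    (low-frequency) region is the long term and the last (high-frequency)
    region the short term.
    """

    short_term_slope: float
    long_term_slope: float
    region_short: tuple[int, int]
    region_long: tuple[int, int]
    boundary: float
    method: str
    intercept_short: float = field(default=np.nan)
    intercept_long: float = field(default=np.nan)


@dataclass(frozen=True)
class CrossoverVerdict:
    """Outcome of comparing both regions' slopes with the boundary.

    ``classification`` is one of ``persistent_both``,
    ``anti_persistent_both``, ``crossover`` (short-term persistent,
    long-term anti-persistent), ``reverse_crossover``, or ``boundary``
    when either slope ties the boundary exactly.
    """

    classification: str
    short_term: str
    long_term: str
    method: str


def bin_loglog(
    p: LogLogPlot,
    bin_width: float = DEFAULT_BIN_WIDTH,
    anchor: float | None = None,
) -> BinnedPlot:
    """Average log-log points within half-open abscissa bins.

    Bins are ``[anchor + k*w, anchor + (k+1)*w)``; the anchor defaults to
    the smallest abscissa, which reproduces the canonical bin counts
    (24 bins for SDA lags 25-8525 ms, 18 for DFA windows 10-512).  Each
    non-empty bin contributes the arithmetic mean of its members' log-log
    coordinates; empty bins are dropped.
    """
    if len(p) == 0:
        raise ValueError("cannot bin an empty plot")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if anchor is None:
        anchor = float(p.log_x[0])
    # nudge guards against points that sit on a bin edge up to float error
    idx = np.floor((p.log_x - anchor) / bin_width + 1e-9).astype(int)
    uniq, inverse, counts = np.unique(idx, return_inverse=True, return_counts=True)
    if uniq.size < 2:
        raise ValueError(
            f"binning produced only {uniq.size} non-empty bin(s); "
            "need at least 2 for any regression"
        )
    sum_x = np.bincount(inverse, weights=p.log_x)
    sum_y = np.bincount(inverse, weights=p.log_y)
    return BinnedPlot(
        x=sum_x / counts,
        y=sum_y / counts,
        bin_indices=uniq,
        counts=counts,
        bin_width=bin_width,
        anchor=anchor,
        source=p.source,
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _resolve_regions(
    b: BinnedPlot,
    region1: tuple[int, int],
    region2: tuple[int, int],
    rescale_short_of: int | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Optionally rescale 1-indexed regions when fewer bins are available.

    The canonical region indices assume a nominal bin count (e.g. 25 for
    PSD).  If the plot has fewer non-empty bins, the indices are shrunk
    proportionally (with a warning) rather than running off the end.
    """
    nbins = len(b)
    nominal = rescale_short_of
    if nominal is not None and nbins < nominal:
        scale = nbins / nominal

        def rescale(r: tuple[int, int]) -> tuple[int, int]:
            lo = max(1, int(round(r[0] * scale)))
            hi = max(lo + 2, int(round(r[1] * scale)))
            return lo, min(hi, nbins)

        new1, new2 = rescale(region1), rescale(region2)
        if new2[0] <= new1[1]:  # keep regions disjoint after shrinking
            new2 = (new1[1] + 1, new2[1])
        warnings.warn(
            f"{b.source}: only {nbins} bins available (nominal {nominal}); "
            f"regions rescaled to {new1} and {new2}",
            stacklevel=3,
        )
        return new1, new2
    return region1, region2


def two_region_slopes(
    b: BinnedPlot,
    region1: tuple[int, int] | None = None,
    region2: tuple[int, int] | None = None,
    method: str | None = None,
    rescale_if_short: bool = False,
) -> SlopePair:
    """Fit separate OLS lines over two 1-indexed inclusive bin ranges.

    ``region1`` covers the small-abscissa end, ``region2`` the large end;
    defaults come from :data:`DEFAULT_REGIONS` for the plot's method.
    For SDA/DFA region1 is the short term; for PSD (frequency abscissa)
    region1 is the long term and region2 the short term.
    """
    method = (method or b.source).upper()
    if method not in BOUNDARIES:
        raise ValueError(f"unknown method {method!r}")
    if region1 is None or region2 is None:
        d1, d2 = DEFAULT_REGIONS[method]
        region1 = region1 or d1
        region2 = region2 or d2
    if rescale_if_short:
        nominal = max(DEFAULT_REGIONS[method][1])
        region1, region2 = _resolve_regions(b, region1, region2, nominal)
    nbins = len(b)
    for lo, hi in (region1, region2):
        if lo < 1 or hi > nbins:
            raise ValueError(
                f"region ({lo}, {hi}) extends past the {nbins} available bins "
                f"(deficit {hi - nbins})"
            )
        if hi - lo + 1 < 3:
            raise ValueError(f"region ({lo}, {hi}) has fewer than 3 bins")
    if region2[0] <= region1[1]:
        raise ValueError(f"regions {region1} and {region2} overlap")
    s1, i1 = _ols_slope(b.x[region1[0] - 1 : region1[1]], b.y[region1[0] - 1 : region1[1]])
    s2, i2 = _ols_slope(b.x[region2[0] - 1 : region2[1]], b.y[region2[0] - 1 : region2[1]])
    if method == "PSD":
        # low frequencies describe the long term, high frequencies the short
        return SlopePair(
            short_term_slope=s2,
            long_term_slope=s1,
            region_short=region2,
            region_long=region1,
            boundary=BOUNDARIES[method],
            method=method,
            intercept_short=i2,
            intercept_long=i1,
        )
    return SlopePair(
        short_term_slope=s1,
        long_term_slope=s2,
        region_short=region1,
        region_long=region2,
        boundary=BOUNDARIES[method],
        method=method,
        intercept_short=i1,
        intercept_long=i2,
    )


def _persistence(slope: float, method: str, boundary: float) -> str:
    if method == "PSD":
        # negative spectral slope: power concentrated at low frequencies
        # (persistence); positive slope: anti-persistence
        if slope == boundary:
            return "boundary"
        return "persistent" if slope < boundary else "anti_persistent"
    if slope == boundary:
        return "boundary"
    return "persistent" if slope > boundary else "anti_persistent"


def classify_crossover(sp: SlopePair) -> CrossoverVerdict:
    """Classify the two-region slope pattern against the method boundary."""
    short = _persistence(sp.short_term_slope, sp.method, sp.boundary)
    long = _persistence(sp.long_term_slope, sp.method, sp.boundary)
    if "boundary" in (short, long):
        cls = "boundary"
    elif short == "persistent" and long == "anti_persistent":
        cls = "crossover"
    elif short == "anti_persistent" and long == "persistent":
        cls = "reverse_crossover"
    elif short == long == "persistent":
        cls = "persistent_both"
    else:
        cls = "anti_persistent_both"
    return CrossoverVerdict(
        classification=cls, short_term=short, long_term=long, method=sp.method
    )


def one_sample_t(values, boundary: float) -> tuple[float, float, int]:
    """One-sample t-test of a slope sample against the method boundary.

    Returns (t, two-sided p, degrees of freedom).  A zero-variance sample
    whose mean differs from the boundary yields t = +/-inf with p = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("one-sample t-test requires at least 2 values")
    sd = v.std(ddof=1)
    df = v.size - 1
    if sd == 0.0:
        if v.mean() == boundary:
            return 0.0, 1.0, df
        return float(np.sign(v.mean() - boundary) * np.inf), 0.0, df
    res = _stats.ttest_1samp(v, popmean=boundary)
    return float(res.statistic), float(res.pvalue), df
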