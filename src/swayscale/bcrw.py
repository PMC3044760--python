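"""Bounded correlated random walk (BCRW) model of COP velocity, and
exact fractional Gaussian noise generation for estimator validation.

The BCRW treats center-of-pressure velocity as a drifting random walk
whose drift direction reverses whenever the absolute velocity exceeds a
threshold ``T``::

    v_t = v_{t-1} + s_{t-1} * drift(v_{t-1}) + b * eps_t

with ``eps_t`` i.i.d. standard Gaussian innovations and ``s`` a sign in
{+1, -1}.  Whenever a step exceeds the threshold (``|v_t| > T``) the
trend sign is reversed so as to drive velocity back toward zero:
``s <- -sign(v_t)``.  (This differs from blindly toggling ``s`` only
when noise produces consecutive exceedances of the same bound, where
toggling would briefly push the velocity *outward*.)  In the default
(proportional) form ``drift(v) = a * |v|`` — the stronger the
velocity, the stronger the trend pushing it onward — which produces
short-term persistent, long-term anti-persistent velocity dynamics: a
cross-over, the statistical fingerprint of a bounded variable.  The
constant form ``drift(v) = a`` is retained for comparison; it bounces
between the limits too systematically to look physiological.

Position is the running integral of velocity.

The fGn generator uses exact circulant embedding (Davies-Harte), so
generated series have the true fractional-Gaussian-noise autocovariance
at the requested Hurst exponent; integrating one yields fractional
Brownian motion.  These serve as ground-truth inputs for validating the
SDA/DFA/spectral slope estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import Series1D, integrate

__all__ = [
    "BcrwParams",
    "BcrwResult",
    "FgnParams",
    "simulate_velocity",
    "simulate_cohort",
    "generate_fgn",
    "generate_fbm",
]

#: Model parameters used throughout for the reference simulation study.
DEFAULT_A = 0.16
DEFAULT_B = 1.6
DEFAULT_T = 10.0
DEFAULT_N = 1024


@dataclass(frozen=True)
class BcrwParams:
    """Parameters of the bounded correlated random walk.

    ``a`` is the trend strength, ``b`` the innovation (noise) strength,
    ``T`` the symmetric velocity threshold at which the trend sign
    reverses, ``n`` the series length, and ``trend_form`` selects the
    drift: ``"proportional"`` (a*|v|, default) or ``"constant"`` (a).
    """

    a: float = DEFAULT_A
    b: float = DEFAULT_B
    T: float = DEFAULT_T
    n: int = DEFAULT_N
    seed: int = 0
    v0: float = 0.0
    trend_form: str = "proportional"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        # a = 0 or b = 0 are permitted as degenerate diagnostic cases
        if not (self.a >= 0 and self.b >= 0 and self.T > 0):
            raise ValueError("require a >= 0, b >= 0, T > 0")
        if abs(self.v0) > self.T:
            raise ValueError(f"|v0| = {abs(self.v0)} exceeds threshold T = {self.T}")
        if self.trend_form not in ("proportional", "constant"):
            raise ValueError(f"unknown trend_form {self.trend_form!r}")


@dataclass(frozen=True)
class BcrwResult:
    """A simulated velocity/position pair with the trend-reversal record.

    ``flips`` lists the time indices t at which ``|velocity[t]| > T``
    (after which the trend sign is set against the exceeded bound);
    ``trend_sign_trace[t]`` is the sign applied when stepping from t to
    t+1.
    """

    velocity: Series1D
    position: Series1D
    flips: np.ndarray
    trend_sign_trace: np.ndarray
    params: BcrwParams = field(repr=False)


def simulate_velocity(p: BcrwParams) -> BcrwResult:
    """Simulate one BCRW velocity series and its integrated position.

    Deterministic for a fixed seed.  The update is sequential (each step's
    drift depends on the previous value and the current trend sign), so
    the loop cannot be vectorized; innovations are drawn in one block.
    """
    rng = np.random.default_rng(p.seed)
    eps = rng.standard_normal(p.n - 1)
    v = np.empty(p.n)
    sign_trace = np.empty(p.n, dtype=np.int8)
    v[0] = p.v0
    s = 1
    proportional = p.trend_form == "proportional"
    flips: list[int] = []
    sign_trace[0] = s
    for t in range(1, p.n):
        prev = v[t - 1]
        drift = p.a * abs(prev) if proportional else p.a
        v[t] = prev + s * drift + p.b * eps[t - 1]
        if abs(v[t]) > p.T:
            flips.append(t)
            s = -1 if v[t] > 0 else 1  # trend now opposes the exceeded bound
        sign_trace[t] = s
    vel = Series1D(v, dt=1.0, label="velocity")
    pos = integrate(vel, 0.0)
    return BcrwResult(
        velocity=vel,
        position=pos,
        flips=np.asarray(flips, dtype=int),
        trend_sign_trace=sign_trace,
        params=p,
    )


def simulate_cohort(
    p: BcrwParams, n_series: int, base_seed: int | None = None
) -> list[BcrwResult]:
    """Simulate independent replicates with seeds base_seed + index.

    With ``base_seed=None`` the seed stored in ``p`` is used as the base.
    Two calls with identical parameters produce bitwise-identical output.
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    base = p.seed if base_seed is None else base_seed
    from dataclasses import replace

    return [simulate_velocity(replace(p, seed=base + i)) for i in range(n_series)]


@dataclass(frozen=True)
class FgnParams:
    """Fractional Gaussian noise parameters: Hurst exponent H in (0, 1),
    length n, marginal standard deviation sigma, RNG seed."""

    H: float
    n: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.H < 1.0):
            raise ValueError(f"H must lie in (0, 1), got {self.H}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def fgn_autocovariance(H: float, lags: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Exact fGn autocovariance gamma(k) = sigma^2/2 (|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * sigma**2 * (
        np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H)
    )


def generate_fgn(p: FgnParams) -> Series1D:
    """Generate exact fractional Gaussian noise by circulant embedding.

    The covariance is embedded in a circulant matrix of size 2n whose
    eigenvalues are obtained by FFT; for the fGn autocovariance these are
    provably nonnegative, making the construction exact (Davies-Harte).
    """
    n = p.n
    gamma = fgn_autocovariance(p.H, np.arange(n + 1), p.sigma)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(row).real
    if np.min(lam) < -1e-8 * np.max(lam):
        raise RuntimeError(
            f"circulant embedding not nonnegative for H={p.H}, n={n} "
            f"(min eigenvalue {np.min(lam):.3e})"
        )
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    rng = np.random.default_rng(p.seed)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0]) * rng.standard_normal()
    w[n] = np.sqrt(lam[n]) * rng.standard_normal()
    re = rng.standard_normal(n - 1)
    im = rng.standard_normal(n - 1)
    half = np.sqrt(lam[1:n] / 2.0) * (re + 1j * im)
    w[1:n] = half
    w[n + 1 :] = np.conj(half[::-1])
    x = np.fft.fft(w).real / np.sqrt(m)
    return Series1D(x[:n], dt=1.0, label="velocity")


def generate_fbm(p: FgnParams) -> Series1D:
    """Fractional Brownian motion: the running integral of exact fGn.

    Returned as a position series of length n (the fGn is generated at
    length n-1 so the motion starts at 0 and has n samples).
    """
    from dataclasses import replace

    noise = generate_fgn(replace(p, n=p.n - 1))
    return integrate(noise, 0.0)
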