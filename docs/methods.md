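# Methods

## Signals and conventions

All analyses operate on `Series1D`: a uniformly sampled real signal
with sampling interval `dt` (seconds) and a role label.  The reference
recording format is a 1024-point COP series at 40 Hz (25.6 s),
acquisition-filtered at 8 Hz; positions are in mm.  Velocity is the
first difference of position, in per-sample units by default — the
model operates in per-sample units, and every scaling slope is
invariant to the constant 1/dt factor, so AAMV and threshold values are
directly comparable with the model's T.  An optional flag converts to
units/s.  Velocity series are never re-filtered after differencing:
differencing amplifies high frequencies, and smoothing them away again
would alter the short-scale slopes that the analysis is about.

`low_pass` (zero-phase 4th-order Butterworth, forward–backward) exists
to emulate the acquisition chain when building synthetic recordings;
empirical inputs are assumed already filtered.  Zero-phase filtering
was chosen because a causal filter's group delay would distort the
serial correlations under study.  The filter's unit DC gain is enforced
exactly by restoring the input mean after filtering (forward–backward
edge transients otherwise shift it by ~1e-5 relative).

## The estimators

**SDA.** For each lag Δt = 1..⌊N/3⌋ samples, the mean of
(x[t+Δt] − x[t])² over *all* overlapping pairs.  The lag cap keeps
every estimate supported by at least three non-overlapping intervals
(341 lags for N = 1024).  Abscissae are expressed in ms.  SDA is
restricted to position series by label; it characterizes the
correlation structure of the *differenced* input.

**DFA.** Profile X(k) = Σ_{i≤k}(x_i − x̄); non-overlapping windows of
length n tile the profile from the start (the tail beyond ⌊N/n⌋·n is
discarded); a least-squares line is removed per window; F(n) is the
RMS of the pooled residuals.  Window lengths run from 10 (below which
the per-window variance estimate is too poor) to 512 (= N/2) on a
~40-point logarithmic grid — the downstream 0.1-decade binning makes
denser grids pointless.  Detrending is first-order only.

**PSD.** Preprocessing in order: (1) subtract the mean; (2) multiply
by the parabolic (Welch) taper W(j) = 1 − (2j/(N+1) − 1)², j = 1..N;
(3) subtract the line through the first and last post-window samples
(bridge detrending), which forces the endpoints to zero.  Windowing
before bridge detrending follows the published order of this
preprocessing chain even though the reverse is more common elsewhere;
robustness of the fitted slopes to the exact endpoint convention of
the taper was checked by the estimator-validation tests.  The spectrum
is a single full-length periodogram (squared modulus at k/(N·dt),
k = 1..N/2, DC excluded) — segment averaging would discard the lowest
frequencies, which a 25.6-s record can barely resolve (f₁ ≈ 0.039 Hz)
and which carry the long-term regime.  Normalization is unscaled
squared modulus; slopes are normalization-invariant.

## Binning, regions, boundaries

Raw log-log points crowd toward large abscissae; fitting them directly
would overweight the long-scale end.  Points are therefore averaged
(arithmetic mean of the log-log coordinates) within half-open
0.1-decade abscissa bins anchored at the smallest abscissa, and all
regressions use the binned points.  This reproduces the canonical bin
counts for the reference geometry: 18 DFA bins (n = 10..512), 25
non-empty PSD bins, 23 non-empty SDA bins (nominally 24; integer lags
leave three sparse low-lag bins empty, one more than the nominal
count assumes — an edge-bin discrepancy without slope consequences).

Two-region regression excludes the central zone where an inflection
may sit: OLS over binned points 1–8 and 17–24 for SDA, 1–6 and 12–18
for DFA, 1–10 and 14–25 for PSD (1-indexed over non-empty bins).  If a
plot yields fewer bins than the nominal count, region indices are
shrunk proportionally with a warning rather than silently truncated.
Boundary values: 1.0 (SDA), 0.5 (DFA), 0.0 (PSD).  For SDA/DFA a slope
above the boundary means persistence; for PSD a negative slope means
persistence.  For PSD the low-frequency region describes the long term
and the high-frequency region the short term.  A short-term-persistent
/ long-term-anti-persistent pair is classified `crossover`; a slope
exactly on the boundary is reported as `boundary`, never silently
assigned to a side.  Persistence of a cohort's mean slope is tested
with a one-sample t-test against the boundary (two-sided).

## The bounded correlated random walk

The generative model treats COP velocity as a drifting random walk,

    v_t = v_{t-1} + s_{t-1} · a·|v_{t-1}| + b·ε_t,   ε_t ~ N(0, 1) i.i.d.,

with v_0 = 0 and s_0 = +1.  The proportional drift a·|v| makes the
trend contribution grow with speed, producing realistic near-Brownian
short-term diffusion instead of a deterministic triangle wave (the
constant-drift variant, retained as `trend_form="constant"`, bounces
between the limits too systematically).  Whenever a step leaves the
band (|v_t| > T), the trend sign is set to oppose the exceeded bound,
s ← −sign(v_t).  Setting rather than toggling the sign matters only
when noise produces consecutive exceedances of the same bound — a
toggle would then briefly push the velocity *outward*, inflating
short-term persistence (ensemble short-term DFA slope 1.54 instead of
1.41 at the reference parameters); the corrective rule is both the
physically sensible reading of threshold-triggered reversal and the
one that reproduces the reference slope signatures.  Position is the
cumulative sum of velocity.

Reference parameters: T = 10, a = 0.16, b = 1.6, N = 1024, chosen to
mimic the shape of empirical COP series.  The update is homogeneous
under (v, T, b) → (cv, cT, cb), so only two of the three scales are
meaningful.  At the reference parameters the walk spends ≈5% of its
time beyond the threshold.  Cohorts use per-series seeds
base_seed + index; everything is deterministic given the seed.
Simulated series are analyzed unfiltered (the model is not an
acquisition chain), with dt = 1 sample; slopes are dt-invariant.

What the model emulates: the two-regime correlation structure of COP
velocity (persistent, slightly sub-Brownian diffusion within the band;
systematic reversals at the band edges) and its consequences for
position.  What it does not: units and amplitudes of real
recordings, AP/ML anisotropy, measurement noise, nonstationarity
across trials, and any neurophysiological mechanism — it is a
phenomenological bounding model, so tests passing on it validate the
estimators and the bounding signature, not a theory of posture.

## fGn/fBm validation oracles

Fractional Gaussian noise of Hurst exponent H is generated exactly by
circulant embedding (Davies–Harte): the length-(n+1) autocovariance
γ(k) = σ²/2(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) is embedded in a
2n-circulant whose FFT eigenvalues are nonnegative for this kernel;
eigenvalues are clipped at −1e-8 relative (an error beyond that aborts
rather than silently distorting the covariance).  fBm is the
cumulative sum of fGn, started at 0.  These series provide ground
truth for estimator consistency: ensemble-mean DFA slopes within ±0.1
of H (fGn) and H+1 (fBm), SDA within ±0.15 of 2H (fBm), and PSD
within ±0.15 of −(2H−1) (fGn) at H ∈ {0.2, 0.5, 0.8}, 50 seeds × 1024
points per cell.

## AAMV

AAMV partitions a velocity series into non-overlapping windows (2 s
default — long enough at 40 Hz that each window contains at least one
local maximum and one local minimum of sway velocity), collects each
window's max and min, and averages their absolute values.  It is even,
homogeneous of degree 1, bounded by the series' absolute maximum, and
on BCRW cohorts increases monotonically with T — the sense in which it
estimates the velocity bound.  The incomplete tail window is
discarded.  Group comparisons (e.g. age × vision designs) can be run
on the per-series AAMV table with any standard ANOVA tool; no bespoke
inference is bundled.

## Pipeline and problem sizes

`run_empirical` applies, per recording and axis: SDA on position, DFA
and PSD on position and velocity, AAMV on velocity; slopes are
aggregated across recordings with t-tests per (method, signal, axis,
region).  Unreadable files are recorded as errors without aborting the
cohort; degenerate series (e.g. constant input, where every log-log
ordinate is undefined) skip the affected stages with warnings and
contribute no rows.  `run_simulation_study` is the simulation twin:
a 100-series cohort analyzed by DFA and PSD on both signals — the
configuration under which the reference slope table (short/long DFA
slopes 1.77/1.25 for position and 1.38/0.35 for velocity;
high/low-frequency PSD slopes −3.53/−1.63 and −1.84/+0.80) is
reproduced by `scripts/acceptance.py`.  Test ensembles elsewhere use
8–50 series, which keeps ensemble means stable to well within the
asserted tolerances while the full suite runs in a few seconds.

## Known limitations

- The empirical arm is validated on simulated recordings only; no
  human data ship with the package, so empirical checks are
  qualitative pattern assertions (cross-over present/absent), not
  numeric reproductions.
- Bin-edge conventions (half-open bins, anchor at the smallest
  abscissa) are one defensible choice among several; bin counts can
  shift by one edge bin under other conventions, slopes negligibly.
- DFA is first-order with forward tiling only; no overlapping-window,
  higher-order, or multifractal variants.
- No automatic cross-over point estimation: region boundaries are
  fixed configuration, as in the protocol this package implements.
- The BCRW is phenomenological; its parameters are not identified
  from data by the package.
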