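import numpy as np
import pytest

from swayscale import (
    BcrwParams,
    FgnParams,
    generate_fbm,
    generate_fgn,
    simulate_cohort,
    simulate_velocity,
)
from swayscale.bcrw import fgn_autocovariance

REFERENCE_PARAMS = dict(a=0.16, b=1.6, T=10.0, n=1024)


def naive_bcrw(a, b, T, n, v0, eps, trend_form="proportional"):
    """Independent hand-stepped oracle of the velocity recurrence."""
    v = [v0]
    s = 1
    flips = []
    for t in range(1, n):
        drift = a * abs(v[-1]) if trend_form == "proportional" else a
        nxt = v[-1] + s * drift + (b * eps[t - 1] if b else 0.0)
        v.append(nxt)
        if abs(nxt) > T:
            flips.append(t)
            s = -1 if nxt > 0 else 1
    return np.array(v), flips


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(n=1), dict(T=-1.0), dict(v0=11.0), dict(trend_form="cubic"), dict(a=-0.1)],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            BcrwParams(**{**REFERENCE_PARAMS, **kwargs})


class TestSimulateVelocity:
    def test_degenerate_all_zero(self):
        res = simulate_velocity(BcrwParams(a=0.0, b=0.0, T=10.0, n=50, v0=0.0))
        np.testing.assert_array_equal(res.velocity.values, 0.0)
        assert res.flips.size == 0

    def test_noise_free_trajectory_matches_hand_stepped_oracle(self):
        p = BcrwParams(a=0.16, b=0.0, T=10.0, n=60, v0=1.0)
        res = simulate_velocity(p)
        expected, flips = naive_bcrw(0.16, 0.0, 10.0, 60, 1.0, None)
        np.testing.assert_allclose(res.velocity.values, expected, rtol=1e-12)
        assert list(res.flips) == flips
        # growth by 1.16 per step until the threshold, then decay by 0.84
        v = res.velocity.values
        first = flips[0]
        np.testing.assert_allclose(v[:first + 1], 1.16 ** np.arange(first + 1), rtol=1e-12)
        np.testing.assert_allclose(v[first + 1], 0.84 * v[first], rtol=1e-12)

    def test_stochastic_trajectory_matches_oracle(self):
        p = BcrwParams(**REFERENCE_PARAMS, seed=7)
        res = simulate_velocity(p)
        eps = np.random.default_rng(7).standard_normal(p.n - 1)
        expected, flips = naive_bcrw(p.a, p.b, p.T, p.n, 0.0, eps)
        np.testing.assert_allclose(res.velocity.values, expected, rtol=1e-12)
        assert list(res.flips) == flips

    def test_flips_iff_exceedance(self):
        res = simulate_velocity(BcrwParams(**REFERENCE_PARAMS, seed=3))
        exceed = set(np.flatnonzero(np.abs(res.velocity.values) > 10.0))
        assert set(res.flips) == exceed

    def test_sign_constant_between_flips(self):
        res = simulate_velocity(BcrwParams(**REFERENCE_PARAMS, seed=5))
        trace = res.trend_sign_trace
        changes = set(np.flatnonzero(np.diff(trace.astype(int)) != 0) + 1)
        assert changes <= set(res.flips)

    def test_position_is_integral_of_velocity(self):
        res = simulate_velocity(BcrwParams(**REFERENCE_PARAMS, seed=1))
        assert len(res.position) == len(res.velocity) + 1
        np.testing.assert_allclose(
            np.diff(res.position.values), res.velocity.values, rtol=1e-12
        )

    def test_seeded_determinism(self):
        a = simulate_velocity(BcrwParams(**REFERENCE_PARAMS, seed=11))
        b = simulate_velocity(BcrwParams(**REFERENCE_PARAMS, seed=11))
        np.testing.assert_array_equal(a.velocity.values, b.velocity.values)

    def test_boundedness(self):
        res = simulate_velocity(BcrwParams(**{**REFERENCE_PARAMS, "n": 10_000}, seed=9))
        v = res.velocity.values
        # one step past the threshold: |v| <= (1+a)*T + b*max|eps|; 8 sd is
        # a generous bound for the seeded innovations
        assert np.max(np.abs(v)) <= 1.16 * 10.0 + 1.6 * 8.0

    def test_long_run_stationarity(self):
        res = simulate_velocity(BcrwParams(**{**REFERENCE_PARAMS, "n": 100_000}, seed=17))
        v = res.velocity.values
        # mean near zero relative to the dispersion of correlated samples
        n_eff = v.size / 100  # conservative decorrelation length
        assert abs(v.mean()) < 3 * v.std() / np.sqrt(n_eff)
        # the walk spends only a small minority of its time beyond the
        # threshold (about 5% at the reference parameters)
        assert np.mean(np.abs(v) > 10.0) < 0.07

    def test_homogeneity_under_joint_rescaling(self):
        base = simulate_velocity(BcrwParams(a=0.16, b=1.6, T=10.0, n=2048, seed=23))
        scaled = simulate_velocity(BcrwParams(a=0.16, b=3.2, T=20.0, n=2048, seed=23))
        np.testing.assert_allclose(
            scaled.velocity.values, 2.0 * base.velocity.values, rtol=1e-9
        )


class TestCohort:
    def test_single_series_matches_direct_call(self):
        p = BcrwParams(**REFERENCE_PARAMS, seed=42)
        cohort = simulate_cohort(p, 1)
        direct = simulate_velocity(p)
        np.testing.assert_array_equal(
            cohort[0].velocity.values, direct.velocity.values
        )

    def test_reproducible_and_distinct(self):
        p = BcrwParams(**REFERENCE_PARAMS)
        c1 = simulate_cohort(p, 3, base_seed=100)
        c2 = simulate_cohort(p, 3, base_seed=100)
        for r1, r2 in zip(c1, c2):
            np.testing.assert_array_equal(r1.velocity.values, r2.velocity.values)
        assert not np.array_equal(c1[0].velocity.values, c1[1].velocity.values)


class TestFgn:
    def test_h_half_is_white(self):
        x = generate_fgn(FgnParams(H=0.5, n=2**14, seed=0)).values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(x.size)

    @pytest.mark.parametrize(
        "H,expected", [(0.8, 2**0.6 - 1), (0.2, 2**-0.6 - 1)]
    )
    def test_lag1_autocorrelation_closed_form(self, H, expected):
        x = generate_fgn(FgnParams(H=H, n=2**14, seed=1)).values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(expected, abs=0.05)

    def test_variance_and_autocovariance(self):
        p = FgnParams(H=0.7, n=2**14, sigma=2.0, seed=4)
        x = generate_fgn(p).values
        assert x.var() == pytest.approx(4.0, rel=0.1)
        lags = np.arange(1, 6)
        expected = fgn_autocovariance(0.7, lags, sigma=2.0)
        for k, g in zip(lags, expected):
            sample = np.mean((x[:-k] - x.mean()) * (x[k:] - x.mean()))
            assert sample == pytest.approx(g, abs=0.2)

    def test_fbm_is_integrated_fgn(self):
        p = FgnParams(H=0.6, n=256, seed=8)
        fbm = generate_fbm(p)
        assert len(fbm) == 256
        assert fbm.values[0] == 0.0
        incr = np.diff(fbm.values)
        fgn = generate_fgn(FgnParams(H=0.6, n=255, seed=8))
        # cumsum-then-diff round trip is exact only up to float cancellation
        np.testing.assert_allclose(incr, fgn.values, atol=1e-9)

    def test_invalid_h_rejected(self):
        with pytest.raises(ValueError):
            FgnParams(H=1.0, n=64)
        with pytest.raises(ValueError):
            FgnParams(H=0.0, n=64)
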