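import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fhrsentinel as fs
from fhrsentinel.features import _interval_stats_window


# ---------------------------------------------------------------------------
# independent brute-force oracle for the interval/window statistics
# ---------------------------------------------------------------------------

def brute_interval_m(x, valid, t, tau, mvf=0.5):
    if not valid[t - tau] or not np.isfinite(x[t - tau]):
        return math.nan
    terms = [x[i] for i in range(t - tau + 1, t + 1) if valid[i] and np.isfinite(x[i])]
    if len(terms) < max(2, math.ceil(mvf * tau)):
        return math.nan
    return sum(v - x[t - tau] for v in terms) / len(terms)


def brute_interval_std(x, valid, t, tau):
    terms = [x[i] for i in range(t - tau + 1, t + 1) if valid[i] and np.isfinite(x[i])]
    if len(terms) < 2:
        return math.nan
    n = len(terms)
    mean = sum(terms) / n
    var = sum(v * v for v in terms) / n - mean * mean
    return math.sqrt(max(var, 0.0))


def brute_window_average(x, valid, tau, which, mvf=0.5):
    nw = len(x)
    vals = []
    for j in range(1, nw // tau + 1):
        t = j * tau
        xe = list(x) + [math.nan]
        ve = list(valid) + [False]
        m = brute_interval_m(xe, ve, t, tau, mvf)
        s = brute_interval_std(xe, ve, t, tau)
        if which == "m":
            v = m
        elif which == "sigma":
            v = s
        else:
            v = m / s if np.isfinite(m) and np.isfinite(s) and s > 0 else math.nan
        vals.append(v)
    ok = [v for v in vals if np.isfinite(v)]
    need = max(1, math.floor(mvf * (nw // tau)))
    if len(ok) < need:
        return math.nan
    return sum(ok) / len(ok)


class TestIntervalStatistics:
    def test_increment_mean_by_hand(self):
        # ((3-2)+(4-2))/2 = 1.5
        assert fs.increment_mean_interval([0, 1, 2, 3, 4], t=4, tau=2) == pytest.approx(1.5)

    def test_increment_mean_constant_signal(self):
        assert fs.increment_mean_interval(np.full(10, 7.0), t=6, tau=3) == 0.0

    def test_increment_mean_with_gap(self):
        # valid terms {0-0, 2-0} -> mean 1
        x = np.array([0.0, 0.0, 2.0])
        assert fs.increment_mean_interval(x, t=2, tau=2) == pytest.approx(1.0)

    def test_increment_mean_invalid_anchor(self):
        x = np.array([np.nan, 1.0, 2.0, 3.0])
        assert math.isnan(fs.increment_mean_interval(x, t=2, tau=2))

    def test_std_by_hand(self):
        # samples {0, 1}: sqrt(0.5 - 0.25) = 0.5
        x = np.array([9.0, 0.0, 1.0])
        assert fs.interval_std(x, t=2, tau=2) == pytest.approx(0.5)

    def test_std_constant_interval_is_zero(self):
        assert fs.interval_std(np.full(6, 3.0), t=4, tau=3) == 0.0

    def test_std_alternating(self):
        x = np.array([0.0, 1.0, -1.0, 1.0, -1.0])
        assert fs.interval_std(x, t=4, tau=4) == pytest.approx(1.0)

    def test_student_ratio_by_hand(self):
        # x=(2,3,4), tau=2, t=2: m=1.5, sigma over {3,4}=0.5, R=3
        assert fs.interval_student_ratio([2.0, 3.0, 4.0], t=2, tau=2) == pytest.approx(3.0)

    def test_student_ratio_degenerate_excluded(self):
        assert math.isnan(fs.interval_student_ratio(np.full(5, 2.0), t=3, tau=2))

    def test_student_ratio_antisymmetry(self, rng):
        x = rng.normal(size=64)
        r1 = fs.interval_student_ratio(x, t=40, tau=8)
        r2 = fs.interval_student_ratio(-x, t=40, tau=8)
        assert r1 == pytest.approx(-r2)


class TestWindowAverage:
    def test_mean_of_interval_values(self):
        # two intervals with per-interval m values 1 and 3 -> 2
        x = np.array([0.0, 0.5, 1.0, 1.0, 2.5, 4.0])
        v1 = fs.increment_mean_interval(x, t=2, tau=2)
        v2 = fs.increment_mean_interval(np.append(x, np.nan), t=4, tau=2)
        got, n = fs.window_feature_average(x, tau=2, which="m")
        assert n >= 2
        assert got == pytest.approx(np.nanmean([v1, v2, math.nan]))

    def test_floor_interval_count(self):
        x = np.arange(20.0)
        _, _ = fs.window_feature_average(x, tau=7, which="m")
        m, s, r = _interval_stats_window(x, np.ones(20, bool), 7, 0.5)
        assert m.size == 20 // 7 == 2

    def test_invalid_interval_skipped(self, rng):
        x = rng.normal(size=30)
        valid = np.ones(30, bool)
        valid[11:21] = False  # kills the 2nd of three tau=10 intervals
        got, n = fs.window_feature_average(x, tau=10, which="sigma", valid=valid)
        m, s, r = _interval_stats_window(x, valid, 10, 0.5)
        assert np.isnan(s[1]) and np.isfinite(s[0]) and np.isfinite(s[2])
        assert got == pytest.approx(np.nanmean(s))

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 17), st.integers(20, 96))
    @settings(max_examples=80, deadline=None)
    def test_oracle_equivalence_random_signals(self, seed, tau, n):
        """Vectorized window statistics match a naive double-loop oracle."""
        r = np.random.default_rng(seed)
        x = r.normal(size=n)
        valid = r.random(n) > 0.2
        x = np.where(valid, x, np.nan)
        for which in ("m", "sigma", "R"):
            want = brute_window_average(x, valid, tau, which)
            got, _ = fs.window_feature_average(x, tau, which, valid)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)


class TestFeatureGridInvariances:
    @pytest.fixture()
    def signal(self, rng):
        from tests.conftest import make_ar1
        return make_ar1(rng, 4800, 0.9, sd=5.0) + 140.0

    def test_shift_invariance(self, signal):
        """Adding a constant leaves m, sigma, R and h unchanged."""
        taus = (8, 20)
        for tau in taus:
            for which in ("m", "sigma", "R"):
                a, _ = fs.window_feature_average(signal, tau, which)
                b, _ = fs.window_feature_average(signal + 37.5, tau, which)
                assert b == pytest.approx(a, abs=1e-9)
            ha = fs.entropy_rate_window(signal, tau)
            hb = fs.entropy_rate_window(signal + 37.5, tau)
            assert hb == pytest.approx(ha, abs=1e-9)

    def test_scale_covariance(self, signal):
        """Multiplying by a > 0 scales m and sigma by a; R and h unchanged."""
        a = 2.75
        for tau in (8, 20):
            m1, _ = fs.window_feature_average(signal, tau, "m")
            m2, _ = fs.window_feature_average(signal * a, tau, "m")
            assert m2 == pytest.approx(a * m1, rel=1e-12)
            s1, _ = fs.window_feature_average(signal, tau, "sigma")
            s2, _ = fs.window_feature_average(signal * a, tau, "sigma")
            assert s2 == pytest.approx(a * s1, rel=1e-12)
            r1, _ = fs.window_feature_average(signal, tau, "R")
            r2, _ = fs.window_feature_average(signal * a, tau, "R")
            assert r2 == pytest.approx(r1, rel=1e-12)
            # h is normalized per window, so exactly scale-free up to the
            # estimator's floating-point path
            h1 = fs.entropy_rate_window(signal, tau)
            h2 = fs.entropy_rate_window(signal * a, tau)
            assert h2 == pytest.approx(h1, abs=0.02)

    def test_window_count_and_timestamps(self):
        series = fs.FhrSeries(sample_rate=4.0, values=np.full(3600 * 4, 140.0),
                              valid_mask=np.ones(3600 * 4, bool))
        cfg = fs.AnalysisConfig(tau_grid=(10, 16))
        grids = fs.compute_feature_grid(series, cfg)
        assert len(grids) == 9  # floor((3600-1200)/300)+1
        assert grids[0].window_center_time == 600.0
        assert grids[3].window_center_time == 3 * 300.0 + 600.0

    def test_constant_series_degenerate(self):
        series = fs.FhrSeries(sample_rate=4.0, values=np.full(4800, 140.0),
                              valid_mask=np.ones(4800, bool))
        g = fs.compute_feature_grid(series, fs.AnalysisConfig(tau_grid=(10,)))[0]
        assert g.m[0] == 0.0 and g.sigma[0] == 0.0
        assert np.isnan(g.R[0]) and np.isnan(g.h[0])

    def test_short_series_empty(self):
        series = fs.FhrSeries(sample_rate=4.0, values=np.full(100, 140.0),
                              valid_mask=np.ones(100, bool))
        assert fs.compute_feature_grid(series) == []

    def test_missing_data_stability(self, rng):
        """20% random dropout changes each window feature by well under the
        across-window spread of that feature."""
        from tests.conftest import make_ar1
        x = make_ar1(rng, 4800 * 3, 0.9, sd=5.0) + 140.0
        full = fs.FhrSeries(sample_rate=4.0, values=x, valid_mask=np.ones(x.size, bool))
        drop = rng.random(x.size) < 0.2
        holey = fs.FhrSeries(sample_rate=4.0, values=np.where(drop, np.nan, x),
                             valid_mask=~drop)
        cfg = fs.AnalysisConfig(tau_grid=(10, 20, 32))
        g_full = fs.compute_feature_grid(full, cfg)
        g_holey = fs.compute_feature_grid(holey, cfg)
        for name, tol in (("m", None), ("sigma", None), ("R", None), ("h", 0.05)):
            a = np.array([g.feature(name) for g in g_full])
            b = np.array([g.feature(name) for g in g_holey])
            spread = np.nanstd(a, axis=0)
            scale = np.maximum(spread, 0.05 * np.nanmean(np.abs(a), axis=0) + 1e-12)
            dev = np.nanmax(np.abs(a - b) / scale)
            # deviations stay small relative to natural window-to-window spread
            assert dev < (5.0 if name == "h" else 2.0), name
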