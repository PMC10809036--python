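import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from szdetect.evaluation import (
    MatchCounts,
    accuracy,
    bootstrap_ci,
    compute_snr,
    f1,
    match_events,
    poisson_baseline,
    snr_performance_regression,
)


def optimal_match_count(manual, detected, tol=1.0):
    """Brute-force maximum one-to-one matching within tolerance (test oracle)."""
    manual, detected = np.asarray(manual, float), np.asarray(detected, float)
    if len(manual) == 0 or len(detected) == 0:
        return 0
    cost = np.abs(manual[:, None] - detected[None, :])
    feasible = cost <= tol
    score = feasible.astype(float)
    ri, ci = linear_sum_assignment(-score)
    return int(feasible[ri, ci].sum())


class TestMatchEvents:
    def test_within_tolerance(self):
        c = match_events([10.0], [10.4])
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_outside_tolerance(self):
        c = match_events([10.0], [11.5])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_mixed(self):
        c = match_events([10.0, 12.0], [10.1, 11.9, 14.0])
        assert (c.tp, c.fp, c.fn) == (2, 1, 0)
        assert c.tp == optimal_match_count([10.0, 12.0], [10.1, 11.9, 14.0])

    def test_count_invariants(self):
        manual, detected = [1.0, 5.0, 9.0], [1.2, 20.0]
        c = match_events(manual, detected)
        assert c.tp + c.fn == len(manual)
        assert c.tp + c.fp == len(detected)

    def test_swap_symmetry(self, rng):
        for _ in range(20):
            a = np.sort(rng.uniform(0, 100, size=6))
            b = np.sort(rng.uniform(0, 100, size=9))
            ab = match_events(a, b)
            ba = match_events(b, a)
            assert (ab.fp, ab.fn) == (ba.fn, ba.fp)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_agrees_with_optimal_on_separated_events(self, data):
        # with events >= 2*tol apart within each list, greedy matching is optimal
        gaps_m = data.draw(st.lists(st.floats(2.1, 30), min_size=0, max_size=8))
        gaps_d = data.draw(st.lists(st.floats(2.1, 30), min_size=0, max_size=8))
        manual = np.cumsum(gaps_m)
        detected = np.cumsum(gaps_d) + data.draw(st.floats(-3, 3))
        c = match_events(manual, detected, tol=1.0)
        assert c.tp == optimal_match_count(manual, detected, tol=1.0)


class TestAccuracyF1:
    def test_published_count_oracle(self):
        c = MatchCounts(tp=139, fp=15, fn=5)
        assert accuracy(c) == pytest.approx(139 / 159, abs=1e-12)
        assert accuracy(c) == pytest.approx(0.8742, abs=5e-5)
        expected_f1 = np.sqrt((139 / 144) * (139 / 154))
        assert f1(c) == pytest.approx(expected_f1, abs=1e-12)
        assert f1(c) == pytest.approx(0.9334, abs=5e-5)

    def test_perfect_detection(self):
        c = MatchCounts(tp=10, fp=0, fn=0)
        assert accuracy(c) == 1.0
        assert f1(c) == 1.0

    def test_product_variant(self):
        c = MatchCounts(tp=139, fp=15, fn=5)
        assert f1(c, variant="product") == pytest.approx((139 / 144) * (139 / 154), abs=1e-12)

    def test_zero_tp(self):
        assert f1(MatchCounts(tp=0, fp=3, fn=2)) == 0.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            accuracy(MatchCounts(0, 0, 0))
        with pytest.raises(ValueError):
            f1(MatchCounts(0, 0, 0))

    def test_bounds(self, rng):
        for _ in range(50):
            c = MatchCounts(*rng.integers(0, 20, size=3))
            if c.tp + c.fp + c.fn == 0:
                continue
            assert 0 <= accuracy(c) <= 1
            assert 0 <= f1(c) <= 1
            assert (accuracy(c) == 1) == (c.fp == 0 and c.fn == 0)


class TestPoissonBaseline:
    def test_empty_manual(self):
        assert poisson_baseline([], 600.0) == 0.0

    def test_analytic_approximation(self):
        # lambda=0.05 Hz, T=600 s: mean F1 ~ 1 - exp(-2*lambda) ~ 0.0952
        rng = np.random.default_rng(0)
        manual = np.sort(rng.uniform(0, 600.0, size=30))
        mean_f1 = poisson_baseline(manual, 600.0, n_reps=300, rng=np.random.default_rng(1))
        assert mean_f1 == pytest.approx(1 - np.exp(-0.1), abs=0.015)

    def test_increasing_in_rate(self):
        rng = np.random.default_rng(2)
        means = []
        for n in (6, 30, 120):
            manual = np.sort(rng.uniform(0, 600.0, size=n))
            means.append(
                poisson_baseline(manual, 600.0, n_reps=200, rng=np.random.default_rng(3))
            )
        assert means[0] < means[1] < means[2]

    def test_structured_manual_below_half(self):
        manual = np.arange(5.0, 600.0, 10.0)
        assert poisson_baseline(manual, 600.0, n_reps=100, rng=4) < 0.5

    def test_duration_validation(self):
        with pytest.raises(ValueError):
            poisson_baseline([1.0], 0.0)


class TestComputeSNR:
    def _baseline(self, n_rep=100):
        return np.tile(np.linspace(0.0, 1.0, 101), n_rep)  # P40-P10 = 0.3

    def test_direct_arithmetic(self):
        x = self._baseline()
        for i in (500, 3000, 7000):
            x[i] = 5.0
        rec = compute_snr(x)
        assert rec.n_peaks == 3
        assert rec.snr == pytest.approx(5.0 / 0.3, rel=0.02)

    def test_no_qualifying_peak_undefined(self):
        rec = compute_snr(self._baseline())
        assert not rec.defined

    def test_scale_invariance(self):
        # scaling trace and prominence threshold together preserves SNR
        x = self._baseline()
        for i in (500, 3000, 7000):
            x[i] = 5.0
        a = compute_snr(x, prominence_min=1.0)
        b = compute_snr(3.0 * x, prominence_min=3.0)
        assert b.snr == pytest.approx(a.snr, rel=1e-9)
        assert b.n_peaks == a.n_peaks

    def test_zero_spread_undefined(self):
        x = np.zeros(1000)
        x[500] = 5.0
        assert not compute_snr(x).defined

    def test_window_applied(self):
        x = self._baseline()
        x[9000] = 5.0
        assert not compute_snr(x, preictal_window=(0, 5000)).defined

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            compute_snr(np.zeros(10), preictal_window=(5, 5))


class TestSNRRegression:
    def test_perfect_linear(self):
        snr = np.linspace(1, 10, 20)
        res = snr_performance_regression(0.05 * snr + 0.2, snr)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.slope == pytest.approx(0.05, abs=1e-9)

    def test_null_relation(self):
        rng = np.random.default_rng(5)
        snr = rng.uniform(1, 10, 50)
        y = rng.uniform(0.4, 0.6, 50)
        res = snr_performance_regression(y, snr)
        assert abs(res.slope) < 0.02
        assert res.p_value > 0.05

    def test_planted_positive_relation(self):
        rng = np.random.default_rng(6)
        snr = rng.uniform(1, 10, 100)
        y = 0.04 * snr + 0.3 + rng.normal(0, 0.05, 100)
        res = snr_performance_regression(y, snr)
        assert res.slope == pytest.approx(0.04, abs=0.015)
        assert res.p_value < 1e-4

    def test_nan_pairs_dropped(self):
        res = snr_performance_regression(
            [0.1, 0.2, 0.3, np.nan], [1.0, 2.0, 3.0, 4.0]
        )
        assert res.n == 3

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            snr_performance_regression([0.1, 0.2, 0.3], [2.0, 2.0, 2.0])


class TestBootstrapCI:
    def test_contains_statistic(self, rng):
        vals = rng.normal(0.7, 0.1, 100)
        lo, hi = bootstrap_ci(vals, np.median, n_boot=2000, rng=7)
        assert lo < np.median(vals) < hi
        assert hi - lo < 0.15

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([np.nan]))
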