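"""Order-i interval statistics, cumulative curves and summaries."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fpwatch as fw
from fpwatch.intervals import (POOL_ALL, POOL_MAX, compute_intervals,
                               duration_for_probability, pool_and_cumulate,
                               summarize_train)

from conftest import random_train


def brute_force_intervals(times: np.ndarray, order: int) -> np.ndarray:
    """Independent oracle: literal enumeration of t(n+i) - t(n)."""
    out = []
    for n in range(len(times) - order):
        out.append(times[n + order] - times[n])
    return np.asarray(out)


@pytest.fixture
def worked_train():
    """The 4-event hand-checked train."""
    return fw.EventTrain("worked", np.array([0.0, 10.0, 25.0, 27.0]), 30.0)


class TestComputeIntervals:
    def test_worked_example_order_one(self, worked_train):
        s = compute_intervals(worked_train, 1)
        np.testing.assert_allclose(s.intervals_s, [10.0, 15.0, 2.0])

    def test_worked_example_order_three(self, worked_train):
        np.testing.assert_allclose(compute_intervals(worked_train, 3).intervals_s,
                                   [27.0])

    def test_empty_when_too_few_events(self, worked_train):
        assert compute_intervals(worked_train, 4).n == 0
        empty = fw.EventTrain("e", np.empty(0), 10.0)
        assert compute_intervals(empty, 1).n == 0

    @pytest.mark.parametrize("order", [1, 2, 3, 4, 5])
    def test_matches_brute_force_oracle(self, order):
        rng = np.random.default_rng(order)
        for _ in range(30):
            train = random_train(rng)
            got = compute_intervals(train, order).intervals_s
            np.testing.assert_array_equal(got,
                                          brute_force_intervals(train.times,
                                                                order))

    def test_paired_order_dominance(self):
        # I_{i+1}(n) >= I_i(n) for every shared index n, exactly
        rng = np.random.default_rng(7)
        for _ in range(20):
            train = random_train(rng)
            for i in range(1, 5):
                a = compute_intervals(train, i).intervals_s
                b = compute_intervals(train, i + 1).intervals_s
                assert np.all(b >= a[:len(b)])


class TestCumulativeCurve:
    def test_counting_worked_example(self, worked_train):
        curve = pool_and_cumulate([compute_intervals(worked_train, 1)])
        assert curve.probability_at(10.0) == pytest.approx(2.0 / 3.0)
        assert curve.probability_at(15.0) == 1.0
        assert curve.probabilities[-1] == 1.0

    def test_identical_muscles_leave_curve_unchanged(self, worked_train):
        s = compute_intervals(worked_train, 1)
        one = pool_and_cumulate([s])
        two = pool_and_cumulate([s, s])
        np.testing.assert_array_equal(one.durations_s, two.durations_s)
        np.testing.assert_array_equal(one.probabilities, two.probabilities)

    def test_per_muscle_max_pooling(self, worked_train):
        other = fw.EventTrain("b", np.array([0.0, 3.0, 6.0]), 30.0)
        sets = [compute_intervals(worked_train, 1),
                compute_intervals(other, 1)]
        curve = pool_and_cumulate(sets, pooling=POOL_MAX)
        # pooled values are the two per-muscle maxima {15, 3}
        assert curve.n_intervals == 2
        assert curve.probability_at(3.0) == 0.5
        assert curve.probability_at(15.0) == 1.0

    def test_all_empty_sets_rejected(self):
        empty = fw.EventTrain("e", np.array([1.0]), 10.0)
        with pytest.raises(ValueError, match="no intervals at order 2"):
            pool_and_cumulate([compute_intervals(empty, 2)])

    def test_mixed_orders_rejected(self, worked_train):
        with pytest.raises(ValueError):
            pool_and_cumulate([compute_intervals(worked_train, 1),
                               compute_intervals(worked_train, 2)])

    def test_poisson_curve_matches_gamma_cdf(self):
        # renewal-theory oracle: order-i intervals of a Poisson process are
        # Gamma(i, lambda); moderate-size check (full-size in acceptance)
        lam = 20.0 / 60.0
        trains = [fw.generate_event_train(
            fw.RenewalSpec("exponential", 20.0, seed=300 + k), 300.0)
            .to_event_train(f"m{k}") for k in range(50)]
        for i in (1, 3):
            pooled = np.concatenate(
                [compute_intervals(t, i).intervals_s for t in trains])
            ks = stats.kstest(pooled, stats.gamma(a=i, scale=1 / lam).cdf)
            assert ks.statistic < 0.05

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(data=st.data())
    def test_curve_monotone_and_terminal_one(self, data):
        ivals = data.draw(st.lists(
            st.floats(min_value=1e-3, max_value=500.0, allow_nan=False),
            min_size=1, max_size=200))
        s = fw.IntervalSet(order=1, intervals_s=np.array(ivals))
        curve = pool_and_cumulate([s], grid_step_s=data.draw(
            st.sampled_from([0.25, 1.0, 3.0])))
        assert np.all(np.diff(curve.probabilities) >= 0)
        assert curve.probabilities[-1] == 1.0
        assert curve.durations_s[-1] >= max(ivals)


class TestDurationForProbability:
    def test_worked_example_quantiles(self, worked_train):
        curve = pool_and_cumulate([compute_intervals(worked_train, 1)])
        assert duration_for_probability(curve, 1.0) == 15.0
        assert duration_for_probability(curve, 0.5) == 10.0

    def test_p_out_of_range_rejected(self, worked_train):
        curve = pool_and_cumulate([compute_intervals(worked_train, 1)])
        for p in (0.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                duration_for_probability(curve, p)

    def test_poisson_p95_matches_analytic_quantile(self):
        # -ln(0.05)/lambda for the exponential order-1 interval
        lam = 30.0 / 60.0
        trains = [fw.generate_event_train(
            fw.RenewalSpec("exponential", 30.0, seed=600 + k), 600.0)
            .to_event_train(f"m{k}") for k in range(30)]
        curve = pool_and_cumulate(
            [compute_intervals(t, 1) for t in trains], grid_step_s=0.1)
        expected = -np.log(0.05) / lam
        assert duration_for_probability(curve, 0.95) == \
            pytest.approx(expected, rel=0.05)

    def test_time_rescaling_equivariance(self, worked_train):
        # scaling all event times by c scales intervals, maxima and
        # duration_for_probability by exactly c
        c = 3.0
        scaled = fw.EventTrain("s", worked_train.times * c,
                               worked_train.recording_duration_s * c)
        base = pool_and_cumulate([compute_intervals(worked_train, 1)],
                                 grid_step_s=0.5)
        big = pool_and_cumulate([compute_intervals(scaled, 1)],
                                grid_step_s=0.5 * c)
        np.testing.assert_allclose(
            compute_intervals(scaled, 2).intervals_s,
            compute_intervals(worked_train, 2).intervals_s * c)
        for p in (0.4, 0.7, 1.0):
            assert duration_for_probability(big, p) == \
                pytest.approx(c * duration_for_probability(base, p))


class TestSummarizeTrain:
    def test_rate(self):
        times = np.linspace(5.0, 295.0, 30)
        train = fw.EventTrain("m", times, 300.0)
        assert summarize_train(train).rate_per_min == pytest.approx(6.0)

    def test_equally_spaced_events_have_zero_skewness(self):
        train = fw.EventTrain("m", np.arange(1.0, 61.0, 2.0), 62.0)
        assert summarize_train(train).skewness == 0.0

    def test_skewness_undefined_below_four_events(self):
        train = fw.EventTrain("m", np.array([1.0, 2.0, 4.0]), 10.0)
        assert np.isnan(summarize_train(train).skewness)

    def test_exponential_skewness_near_two(self):
        truth = fw.generate_event_train(
            fw.RenewalSpec("exponential", 60.0, seed=4), 3600.0)
        s = summarize_train(truth.to_event_train("m"))
        assert s.skewness == pytest.approx(2.0, abs=0.4)

    def test_max_interval_nondecreasing_in_order(self, worked_train):
        s = summarize_train(worked_train)
        maxima = [s.max_interval_per_order_s[i] for i in (1, 2, 3)]
        assert maxima == sorted(maxima)
        assert np.isnan(s.max_interval_per_order_s[4])
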