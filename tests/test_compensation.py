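import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.vq import kmeans2

import bandevents as be
from bandevents.compensation import (
    BUCKET_THRESHOLDS,
    BucketState,
    FIFO_SIZE,
    bucket_hr,
    bucket_index,
    bucket_majority,
    bucket_update,
    kmeans_compensate,
    median_compensate,
    _lloyd_1d,
)


def periods_series(periods, start=0.0):
    periods = np.asarray(periods, dtype=float)
    times = start + np.cumsum(periods)
    return be.PeriodSeries(times=times, periods=periods)


class TestMedianCompensate:
    def test_missed_single_beat_corrected_to_double_rate(self):
        """A 32 bpm outlier inside a 70 bpm rhythm is read as one missed beat
        and corrected to 64 bpm."""
        hist = [60.0 / 70.0] * 30
        ps = periods_series(hist + [60.0 / 32.0])
        out = median_compensate(ps)
        assert len(out) == 1
        assert out.periods[0] == pytest.approx(60.0 / 64.0)
        assert 60.0 / out.periods[0] == pytest.approx(64.0)

    def test_period_at_median_unchanged(self):
        ps = periods_series([0.8] * 31)
        out = median_compensate(ps)
        assert out.periods[0] == pytest.approx(0.8)

    def test_warmup_produces_no_output(self):
        assert len(median_compensate(periods_series([0.7] * 30))) == 0
        assert len(median_compensate(periods_series([0.7] * 5))) == 0

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.01, 4.999), st.floats(0.3, 1.2))
    def test_exhaustive_candidate_oracle(self, mult, base):
        """Output equals brute-force argmin over the five harmonic candidates
        and the divisor is an integer 1..5, so output lies in [h/5, h]."""
        h = mult * base
        ps = periods_series([base] * 30 + [h])
        out = median_compensate(ps)
        ks = np.array([1, 2, 3, 4, 5])
        k_star = ks[np.argmin(np.abs(h - ks * base))]
        assert out.periods[0] == pytest.approx(h / k_star)
        assert h / 5 - 1e-12 <= out.periods[0] <= h + 1e-12

    def test_history_is_previous_30_events(self):
        # a slow drift: the median must come from the trailing window, not
        # the global series
        periods = [0.5] * 30 + [1.0] * 30 + [2.0]
        out = median_compensate(periods_series(periods))
        # by the last event the trailing 30 are all 1.0 -> 2.0 maps to k=2
        assert out.periods[-1] == pytest.approx(1.0)


class TestKMeans:
    def test_identical_periods_degenerate(self):
        ps = periods_series([0.7] * 20)
        res = kmeans_compensate(ps, 60.0)
        assert len(res) == 1
        assert res[0].hr_dominant == pytest.approx(60 / 0.7)
        assert res[0].hr_compensated == pytest.approx(60 / 0.7)

    def test_doubled_outliers_folded_back(self):
        ps = periods_series([0.7] * 18 + [1.4] * 2)
        res = kmeans_compensate(ps, 60.0)[0]
        # 1.4 * (1/2) = 0.7 exactly: compensated mean period is 0.7
        assert res.hr_compensated == pytest.approx(60 / 0.7)
        assert res.hr_dominant == pytest.approx(60 / 0.7)
        assert res.n_periods == 20

    def test_simulated_30pct_missed_beats(self):
        rng = np.random.default_rng(5)
        periods = np.full(60, 0.7)
        doubled = rng.random(60) < 0.3
        periods[doubled] *= 2
        ps = periods_series(periods)
        for res in kmeans_compensate(ps, 60.0):
            assert abs(res.hr_compensated - 60 / 0.7) < 1.0

    def test_window_with_too_few_periods_skipped(self):
        ps = periods_series([0.7, 0.7])
        assert kmeans_compensate(ps, 15.0) == []

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            kmeans_compensate(periods_series([0.7] * 5), 45.0)

    def test_lloyd_matches_scipy_on_separated_clusters(self):
        """Independent cross-check: scipy's kmeans2 from the same seeds finds
        the same partition on well-separated 1-D data."""
        rng = np.random.default_rng(6)
        x = np.concatenate([
            rng.normal(0.7, 0.01, 25),
            rng.normal(1.4, 0.01, 8),
            rng.normal(2.1, 0.01, 4),
        ])
        seeds = np.array([0.7, 1.4, 2.1])
        ours = _lloyd_1d(x, seeds)
        _, labels = kmeans2(x.reshape(-1, 1), seeds.reshape(-1, 1), minit="matrix", seed=1)
        assert np.array_equal(ours, labels)


class TestBucketIndex:
    @pytest.mark.parametrize(
        "period, index",
        [(0.67, 5), (0.40, 1), (0.41, 2), (3.2, 14), (5.0, 14), (0.05, 1), (0.7, 5), (0.71, 6)],
    )
    def test_first_threshold_at_or_above(self, period, index):
        assert bucket_index(period) == index

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            bucket_index(0.0)


class TestBucketUpdate:
    def test_streaming_state_equals_recomputed_histogram(self):
        rng = np.random.default_rng(7)
        state = BucketState()
        fifo = []
        for period in rng.uniform(0.3, 3.5, size=50):
            bucket_update(state, period)
            fifo.append(period)
            fifo = fifo[-FIFO_SIZE:]
            state.check()
            # from-scratch histogram of the FIFO contents
            idx = [bucket_index(p) - 1 for p in fifo]
            for b in range(len(BUCKET_THRESHOLDS)):
                members = [p for p, i in zip(fifo, idx) if i == b]
                assert state.counters[b] == len(members)
                if members:
                    assert state.means[b] == pytest.approx(np.mean(members))
                else:
                    assert state.means[b] == 0.0

    def test_fifo_capacity(self):
        state = BucketState()
        for _ in range(100):
            bucket_update(state, 0.7)
        assert state.counters.sum() == FIFO_SIZE


def fill_state(periods):
    state = BucketState()
    for p in periods:
        bucket_update(state, p)
    return state


def brute_force_majority(counters, means):
    """Exhaustive scan oracle for the majority rules."""
    for width, limit in ((1, 20), (2, 15), (3, 15)):
        best = None  # (count, start)
        for start in range(len(counters) - width + 1):
            total = sum(counters[start : start + width])
            if total > limit and (best is None or total > best[0]):
                best = (total, start)
        if best is not None:
            total, start = best
            win = range(start, start + width)
            idx = max(win, key=lambda j: (counters[j], -j))
            mean = sum(counters[j] * means[j] for j in win) / total
            return idx, mean
    return None


class TestBucketMajority:
    def test_single_majority(self):
        state = fill_state([0.85] * 21 + [1.7] * 9)
        maj = bucket_majority(state)
        assert maj.rule == "single"
        assert maj.index == 6  # 0.85 -> 0.9 bucket (1-based 7)
        assert maj.mean_period_s == pytest.approx(0.85)

    def test_dual_combined_majority(self):
        # straddling the 0.7 threshold: no single bucket > 20
        state = fill_state([0.69] * 10 + [0.71] * 8 + [1.4] * 12)
        maj = bucket_majority(state)
        assert maj.rule == "dual"
        assert maj.index == 4
        assert maj.mean_period_s == pytest.approx((10 * 0.69 + 8 * 0.71) / 18)

    def test_no_majority(self):
        state = fill_state([0.45, 0.8, 1.3, 2.0, 3.0])
        assert bucket_majority(state) is None

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**32 - 1))
    def test_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        state = fill_state(rng.uniform(0.3, 3.5, size=30) ** rng.uniform(0.5, 2.0))
        maj = bucket_majority(state)
        expected = brute_force_majority(state.counters.tolist(), state.means.tolist())
        if expected is None:
            assert maj is None
        else:
            assert (maj.index, pytest.approx(maj.mean_period_s)) == expected


class TestBucketHr:
    def test_uniform_fifo(self):
        state = fill_state([0.70] * 30)
        assert bucket_hr(state) == pytest.approx(60 / 0.7)

    def test_harmonic_bucket_included_when_rate_matches(self):
        # majority at 0.70 plus five doubled periods: 1.4/2 = 0.7 keeps HR
        state = fill_state([0.70] * 25 + [1.40] * 5)
        assert bucket_hr(state) == pytest.approx(60 / 0.7)

    def test_distant_bucket_excluded_when_rate_mismatches(self):
        # 2.8/2 = 1.4 s (42.9 bpm) and 2.8/3 = 0.933 s (64.3 bpm) are both
        # more than 20 bpm from 85.7 bpm: the bucket is ignored
        state = fill_state([0.70] * 26 + [2.8] * 4)
        assert bucket_hr(state) == pytest.approx(60 / 0.7)

    def test_small_harmonic_buckets_ignored(self):
        # three elements only (not > 3): never folded in
        state = fill_state([0.70] * 27 + [1.4] * 3)
        assert bucket_hr(state) == pytest.approx(60 / 0.7)

    def test_no_majority_returns_last_valid(self):
        state = fill_state([0.70] * 30)
        first = bucket_hr(state)
        # scatter the FIFO so no majority remains
        for p in [0.42, 0.47, 0.55, 0.65, 0.75, 0.85, 0.95, 1.1, 1.4, 1.8] * 3:
            bucket_update(state, p)
        assert bucket_majority(state) is None
        assert bucket_hr(state) == pytest.approx(first)

    def test_fresh_state_has_no_estimate(self):
        assert bucket_hr(BucketState()) is None


class TestParameterRecovery:
    def test_doubled_periods_recovered_by_both_streaming_algorithms(self):
        """Constant 85 bpm with 30% of periods doubled: both compensators
        converge to the true rate; the naive mean-period HR is ~23% low."""
        rng = np.random.default_rng(8)
        true_period = 60.0 / 85.0
        periods = np.full(400, true_period)
        periods[rng.random(400) < 0.3] *= 2
        ps = periods_series(periods)

        med = median_compensate(ps)
        assert abs(60.0 / med.periods.mean() - 85.0) < 2.0

        times, rates = be.bucket_hr_series(ps)
        assert len(rates) > 300
        assert abs(np.mean(rates[50:]) - 85.0) < 2.0

        naive = be.naive_mean_hr(ps)
        assert naive < 0.85 * 85.0  # biased low by more than 15%
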