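import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bandevents as be
from bandevents.processing import merge_split_respiratory, classify, reject_false_positives
from tests.conftest import random_event_stream

N = 200.0


def stream_of(events):
    return be.EventStream(
        N,
        T=[e[0] for e in events],
        H=[e[1] for e in events],
        V1=[e[2] for e in events],
        V2=[e[3] for e in events],
    )


class TestMergeSplitRespiratory:
    def test_wide_gap_pair_unchanged(self):
        # P = 4.05 - 150/200 - 3.0 = 0.30 s -> P*N = 60 >= 20: untouched
        s = stream_of([(3.0, 60, 10.0, 4.0), (4.05, 150, 9.0, 2.0)])
        out = merge_split_respiratory(s)
        assert np.array_equal(out.T, s.T)
        assert np.array_equal(out.H, s.H)

    def test_narrow_gap_pair_merged_with_blip(self):
        # P = 3.84 - 0.75 - 3.0 = 0.09 s -> P*N = 18 < 20: merge
        s = stream_of([(3.0, 60, 10.0, 4.0), (3.84, 150, 9.0, 2.0)])
        out = merge_split_respiratory(s)
        assert len(out) == 2
        blip, merged = out[0], out[1]
        assert blip.H == 18
        assert blip.T == pytest.approx(3.09)
        assert blip.V1 == pytest.approx(9.0)  # V1 taken from E2
        assert blip.V2 == pytest.approx(4.0)  # V2 taken from E1
        assert merged.H == 210
        assert merged.T == pytest.approx(3.84)
        assert merged.V1 == pytest.approx(10.0)
        assert merged.V2 == pytest.approx(2.0)

    def test_chain_of_three_merges_left_to_right(self):
        # three long events, each gap 10 samples: one respiratory + two blips
        h = 100
        t1 = 1.0
        t2 = t1 + 10 / N + h / N
        t3 = t2 + 10 / N + h / N
        s = stream_of([(t1, h, 1.0, 2.0), (t2, h, 3.0, 4.0), (t3, h, 5.0, 6.0)])
        out = merge_split_respiratory(s)
        assert sorted(out.H.tolist()) == [10, 10, 300]
        resp = out[int(np.argmax(out.H))]
        assert resp.T == pytest.approx(t3)
        assert resp.V1 == pytest.approx(1.0)
        assert resp.V2 == pytest.approx(6.0)

    def test_merge_conserves_respiratory_period(self):
        rng = np.random.default_rng(3)
        s = random_event_stream(rng, 50)
        out = merge_split_respiratory(s)
        params = be.ProcessingParams()
        # blips created by merging carry the gap samples, so total H of long
        # events is conserved
        assert out.H[out.H > params.h_split].sum() >= s.H[s.H > params.h_split].sum()

    def test_short_events_never_merged(self):
        # H <= 20 on either side: pair is left alone for classification
        s = stream_of([(1.0, 15, 0.0, 0.0), (1.2, 150, 0.0, 0.0)])
        out = merge_split_respiratory(s)
        assert np.array_equal(out.H, s.H)


class TestClassify:
    def test_threshold_boundary(self):
        s = stream_of([(1.0, 20, 0, 0), (2.0, 21, 0, 0)])
        ce = classify(s)
        assert ce.cardiac.H.tolist() == [20]
        assert ce.respiratory.H.tolist() == [21]

    def test_empty_stream(self):
        ce = classify(be.EventStream(N))
        assert len(ce.respiratory) == 0 and len(ce.cardiac) == 0

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(4)
        s = random_event_stream(rng, 80)
        ce = classify(s)
        assert np.array_equal(ce.respiratory.H, s.H[s.H > 20])
        assert np.array_equal(ce.cardiac.H, s.H[s.H <= 20])
        assert len(ce.respiratory) + len(ce.cardiac) == len(s)


class TestRejectFalsePositives:
    def _cardiac(self, events):
        return be.ClassifiedEvents(respiratory=be.EventStream(N), cardiac=stream_of(events))

    def test_close_cardiac_pair_keeps_larger_H(self):
        ce = self._cardiac([(1.0, 5, 0, 0), (1.2, 9, 0, 0)])  # 0.2 s < 1/3 s
        out = reject_false_positives(ce)
        assert out.cardiac.H.tolist() == [9]

    def test_separated_respiratory_pair_kept(self):
        ce = be.ClassifiedEvents(
            respiratory=stream_of([(1.0, 100, 0, 0), (2.5, 100, 0, 0)]), cardiac=be.EventStream(N)
        )
        out = reject_false_positives(ce)
        assert len(out.respiratory) == 2

    def test_triplet_sequential_sweep(self):
        # 0.0/0.2/0.4 with H 9/5/7: middle dropped, then 0.4 vs 0.0 is fine
        ce = self._cardiac([(0.5, 9, 0, 0), (0.7, 5, 0, 0), (0.9, 7, 0, 0)])
        out = reject_false_positives(ce)
        assert out.cardiac.T.tolist() == [0.5, 0.9]
        assert out.cardiac.H.tolist() == [9, 7]

    def test_tie_drops_later_event(self):
        ce = self._cardiac([(1.0, 5, 0, 0), (1.1, 5, 0, 0)])
        out = reject_false_positives(ce)
        assert out.cardiac.T.tolist() == [1.0]

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 60))
    def test_idempotent_and_gap_respecting(self, seed, n):
        rng = np.random.default_rng(seed)
        # dense stream to provoke rejections
        h = rng.integers(1, 40, size=n)
        t = np.cumsum(rng.uniform(0.05, 0.8, size=n))
        s = be.EventStream(N, T=t, H=h, V1=np.zeros(n), V2=np.zeros(n))
        ce = classify(s)
        once = reject_false_positives(ce)
        twice = reject_false_positives(once)
        for attr in ("respiratory", "cardiac"):
            a, b = getattr(once, attr), getattr(twice, attr)
            assert np.array_equal(a.T, b.T) and np.array_equal(a.H, b.H)
        params = be.ProcessingParams()
        if len(once.cardiac) > 1:
            assert np.all(np.diff(once.cardiac.T) >= params.min_card_interval_s - 1e-12)
        if len(once.respiratory) > 1:
            assert np.all(np.diff(once.respiratory.T) >= params.min_resp_interval_s - 1e-12)


def test_pure_respiratory_signal_has_no_cardiac_events(resp_only_cfg):
    series, truth = be.generate_band_signal(resp_only_cfg)
    ce = be.process_events(be.generate_events(series))
    assert len(ce.cardiac) == 0
    assert abs(len(ce.respiratory) - len(truth.breath_peak_times)) <= 1
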