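"""Metric tests: PRD, compression summary, beat matching, SE/+P, HV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwmecg.metrics import (
    MatchResult,
    compression_summary,
    detection_stats,
    hrv_error,
    match_beats,
    prd,
)


class TestPrd:
    def test_identity_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert prd(x, x) == 0.0

    def test_hand_computed_value(self):
        assert prd([4.0, 3.0], [4.0, 0.0]) == pytest.approx(60.0)

    def test_total_error_is_hundred(self):
        assert prd([3.0, 4.0], [0.0, 0.0]) == pytest.approx(100.0)

    def test_scale_invariance(self):
        x = np.array([3.0, -1.0, 4.0, 1.0])
        xh = x + 0.25
        assert prd(7.5 * x, 7.5 * xh) == pytest.approx(prd(x, xh))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prd([1.0], [1.0, 2.0])

    def test_all_zero_original_rejected(self):
        with pytest.raises(ValueError):
            prd([0.0, 0.0], [1.0, 1.0])


class TestCompressionSummary:
    def test_abstract_operating_point(self):
        # 16-bit storage to 4-bit codes at PRD 0.33% gives BCR 4, QS ~12
        s = compression_summary(16, 4, 0.33, bytes_before=200, bytes_after=20)
        assert s.bcr == 4.0
        assert s.qs == pytest.approx(4.0 / 0.33)
        assert s.space_saving == pytest.approx(90.0)

    def test_unit_ratio(self):
        assert compression_summary(16, 16, 1.0, 10, 10).bcr == 1.0

    def test_perfect_reconstruction_flags_infinite_qs(self):
        assert math.isinf(compression_summary(16, 4, 0.0, 10, 5).qs)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            compression_summary(16, 0, 1.0, 10, 5)
        with pytest.raises(ValueError):
            compression_summary(16, 4, 1.0, 0, 5)


class TestMatchBeats:
    def test_partial_match(self):
        m = match_beats([100, 500], [110, 900], tolerance=54)
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)
        assert m.matched_pairs == [(100, 110)]

    def test_empty_detection(self):
        m = match_beats([10, 20, 30], [], tolerance=5)
        assert (m.tp, m.fp, m.fn) == (0, 0, 3)

    def test_perfect_detection(self):
        m = match_beats([10, 20, 30], [10, 20, 30], tolerance=5)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)

    def test_one_to_one_nearest(self):
        # two detections near one reference: only the nearer one matches
        m = match_beats([100], [95, 104], tolerance=10)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.matched_pairs == [(100, 104)]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            match_beats([5, 5], [1], tolerance=2)

    @settings(deadline=None, max_examples=50)
    @given(data=st.data())
    def test_counts_consistent(self, data):
        ref = sorted(
            data.draw(st.sets(st.integers(0, 5000), max_size=40))
        )
        det = sorted(
            data.draw(st.sets(st.integers(0, 5000), max_size=40))
        )
        m = match_beats(ref, det, tolerance=50)
        assert m.tp == len(m.matched_pairs)
        assert m.tp + m.fn == len(ref)
        assert m.tp + m.fp == len(det)
        for r, d in m.matched_pairs:
            assert abs(r - d) <= 50


class TestDetectionStats:
    def test_hand_computed(self):
        se, pp = detection_stats(MatchResult(tp=99, fp=2, fn=1))
        assert se == pytest.approx(99.0)
        assert pp == pytest.approx(100.0 * 99 / 101)

    def test_perfect(self):
        assert detection_stats(MatchResult(tp=5, fp=0, fn=0)) == (100.0, 100.0)

    def test_total_miss(self):
        se, pp = detection_stats(MatchResult(tp=0, fp=5, fn=10))
        assert (se, pp) == (0.0, 0.0)

    def test_empty_denominators_flagged(self):
        se, pp = detection_stats(MatchResult(tp=0, fp=0, fn=0))
        assert math.isnan(se) and math.isnan(pp)


class TestHrvError:
    FS = 360.0
    MIN = int(360 * 60)

    def test_identical_streams_zero(self):
        peaks = np.arange(100, self.MIN * 2, 400)
        hv, errors = hrv_error(peaks, peaks, self.FS)
        assert hv == 0.0
        assert all(e == 0.0 for e in errors)

    def test_two_window_hand_example(self):
        # window 1 mean R-R: 360 vs 366; window 2: 360 vs 362 -> HV = 4
        ref = np.concatenate([
            np.arange(0, self.MIN - 400, 360),
            self.MIN + np.arange(0, self.MIN - 400, 360),
        ])
        rec = np.concatenate([
            np.arange(0, self.MIN - 400, 366),
            self.MIN + np.arange(0, (self.MIN - 400) // 362 * 362 + 1, 362),
        ])
        hv, errors = hrv_error(ref, rec, self.FS)
        assert errors == [pytest.approx(6.0), pytest.approx(2.0)]
        assert hv == pytest.approx(4.0)

    def test_single_window(self):
        ref = np.arange(0, 10_000, 300)
        hv, errors = hrv_error(ref, ref, self.FS)
        assert hv == 0.0 and len(errors) == 1

    def test_sparse_window_skipped(self):
        ref = np.array([100, 460, 820, self.MIN + 500])  # 2nd window: 1 beat
        hv, errors = hrv_error(ref, ref, self.FS)
        assert errors[1] is None
        assert hv == 0.0
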