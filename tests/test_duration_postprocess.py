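import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynamos import (
    DurationStats,
    PostprocessConfig,
    SegmentList,
    duration_stats,
    durations,
    postprocess,
    segments_to_mask,
    try_merge,
    try_split,
)

from conftest import make_series

BAND = DurationStats(median=1.0, lower=0.8, upper=1.4)


def flat_omega(n=1000, level=1.0):
    return make_series(np.full(n, level))


def two_bump_omega(n, minima_at):
    """Non-negative signal with strict interior local minima exactly at ``minima_at``."""
    omega = np.ones(n)
    for m in minima_at:
        omega[m - 1 : m + 2] = [0.5, 0.2, 0.5]
    return make_series(omega)


class TestDurations:
    def test_single_one_second(self):
        assert durations(SegmentList(((0, 100),), fs=100)) == pytest.approx([1.0])

    def test_empty(self):
        assert durations(SegmentList((), fs=100)) == []

    def test_pair(self):
        assert durations(SegmentList(((0, 50), (60, 200)), fs=100)) == pytest.approx([0.5, 1.4])


class TestDurationStats:
    def test_uniform(self):
        st_ = duration_stats([1, 1, 1], PostprocessConfig(alpha=0.8, beta=1.4))
        assert (st_.median, st_.lower, st_.upper) == (1.0, 0.8, 1.4)

    def test_odd_median(self):
        assert duration_stats([0.5, 1.0, 2.0], PostprocessConfig()).median == 1.0

    def test_even_median_mean_of_middle(self):
        assert duration_stats([1.0, 2.0], PostprocessConfig()).median == 1.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            duration_stats([], PostprocessConfig())


class TestTryMerge:
    def test_merges_with_nearest_when_sum_in_band(self):
        # durations [1.0, 0.3, 0.8]; gaps 0.2 s and 0.1 s around the short one
        segs = SegmentList(((0, 100), (120, 150), (160, 240)), fs=100)
        out, merged = try_merge(segs, 1, flat_omega(), BAND)
        assert merged
        assert out.segments == ((0, 100), (120, 240))

    def test_rejects_when_sum_exceeds_band(self):
        # 0.3 s outlier whose only neighbour lasts 1.3 s (sum 1.6 > 1.4)
        segs = SegmentList(((0, 130), (150, 180)), fs=100)
        out, merged = try_merge(segs, 1, flat_omega(), BAND)
        assert not merged
        assert out.segments == segs.segments

    def test_single_segment_has_no_partner(self):
        segs = SegmentList(((0, 30),), fs=100)
        out, merged = try_merge(segs, 0, flat_omega(), BAND)
        assert not merged and out.segments == segs.segments

    def test_requires_short_outlier(self):
        segs = SegmentList(((0, 100), (120, 220)), fs=100)
        with pytest.raises(ValueError, match="not a short-duration outlier"):
            try_merge(segs, 0, flat_omega(), BAND)


class TestTrySplit:
    def test_splits_at_single_interior_minimum(self):
        # 2.0 s segment, two equal bumps meeting at sample 100
        omega = make_series(np.abs(np.sin(np.pi * np.arange(400) / 100)) + 0.01)
        segs = SegmentList(((0, 200),), fs=100)
        out, split = try_split(segs, 0, omega, BAND)
        assert split
        assert out.segments == ((0, 100), (100, 200))

    def test_monotone_segment_has_no_split_point(self):
        omega = make_series(np.linspace(0.1, 2.0, 300))
        segs = SegmentList(((0, 200),), fs=100)
        out, split = try_split(segs, 0, omega, BAND)
        assert not split and out.segments == segs.segments

    def test_rejects_unbalanced_pieces(self):
        # 3.5 s segment, lone minimum 1.0 s after onset -> pieces 1.0 / 2.5
        segs = SegmentList(((0, 350),), fs=100)
        out, split = try_split(segs, 0, two_bump_omega(400, [100]), BAND)
        assert not split and out.segments == segs.segments

    def test_balanced_choice_among_admissible_minima(self):
        # minima at 80, 100, 130; only 100 balances a 2.0 s segment best
        segs = SegmentList(((0, 200),), fs=100)
        out, split = try_split(segs, 0, two_bump_omega(300, [80, 100, 130]), BAND)
        assert split
        assert out.segments == ((0, 100), (100, 200))

    def test_requires_long_outlier(self):
        segs = SegmentList(((0, 100),), fs=100)
        with pytest.raises(ValueError, match="not a long-duration outlier"):
            try_split(segs, 0, flat_omega(), BAND)


class TestPostprocess:
    CFG = PostprocessConfig(alpha=0.8, beta=1.4)

    def test_no_outliers_is_fixed_point(self):
        segs = SegmentList(((0, 100), (150, 250), (300, 400), (450, 550)), fs=100)
        out = postprocess(segs, flat_omega(), self.CFG)
        assert out.segments == segs.segments

    def test_merge_fixture_full_trace(self):
        # [1.0, 0.3, 0.8] -> short outlier merges across its 0.1 s gap -> [1.0, 1.2]
        segs = SegmentList(((0, 100), (120, 150), (160, 240)), fs=100)
        out = postprocess(segs, flat_omega(), self.CFG)
        assert out.segments == ((0, 100), (120, 240))
        assert durations(out) == pytest.approx([1.0, 1.2])

    def test_long_two_bump_segment_is_split(self):
        omega = np.full(1200, 0.01)
        for start in (0, 150, 700, 900):  # 1.0 s movements
            omega[start : start + 100] = 1.0
        omega[300:500] = 1.0  # 2.0 s two-bump movement
        omega[399:402] = [0.5, 0.2, 0.5]
        segs = SegmentList(((0, 100), (150, 250), (300, 500), (700, 800), (900, 1000)), fs=100)
        out = postprocess(segs, make_series(omega), self.CFG)
        assert len(out) == len(segs) + 1
        assert (300, 400) in out.segments and (400, 500) in out.segments

    def test_idempotent_on_own_output(self):
        segs = SegmentList(((0, 100), (120, 150), (160, 240), (400, 700)), fs=100)
        omega = two_bump_omega(800, [550])
        once = postprocess(segs, omega, self.CFG)
        twice = postprocess(once, omega, self.CFG)
        assert twice.segments == once.segments

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_terminates_with_valid_output_on_random_lists(self, seed):
        rng = np.random.default_rng(seed)
        n = 3000
        mask = np.zeros(n, dtype=bool)
        pos = 0
        while pos < n - 20:
            length = int(rng.integers(5, 300))
            gap = int(rng.integers(5, 200))
            mask[pos : min(pos + length, n)] = True
            pos += length + gap
        omega = np.abs(np.convolve(rng.normal(size=n), np.hanning(31), mode="same")) + 0.01
        from dynamos import mask_to_segments

        segs = mask_to_segments(mask, fs=100)
        if len(segs) == 0:
            return
        out = postprocess(segs, make_series(omega), self.CFG)
        # sorted, non-overlapping, within bounds
        prev = 0
        for a, b in out:
            assert 0 <= a < b
            assert a >= prev
            prev = b
        # coverage: output covers all input samples; extra cover only comes from merged gaps
        in_mask = segments_to_mask(segs, n)
        out_mask = segments_to_mask(out, n)
        assert (out_mask | in_mask == out_mask).all()

    def test_adversarial_all_outlier_list_terminates(self):
        # alternating tiny and huge durations: every segment is an outlier
        segs = []
        pos = 0
        for i in range(40):
            length = 5 if i % 2 == 0 else 400
            segs.append((pos, pos + length))
            pos += length + 10
        omega = flat_omega(pos + 10)
        out = postprocess(SegmentList(tuple(segs), fs=100), omega, self.CFG)
        assert len(out) >= 1
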