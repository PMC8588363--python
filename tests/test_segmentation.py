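"""Epoching arithmetic, SampEn oracle equivalence, alignment and labeling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xfall import segmentation as seg
from xfall import synthetic_data as sd
from xfall.signal_io import LABEL_ADL, LABEL_FALL, AccelTrace


def brute_force_sampen(x, m=2, r=0.2):
    """Independent O(n^2) template-counting implementation of SampEn."""
    x = list(map(float, x))
    n = len(x)
    sdev = float(np.std(x))
    if sdev == 0.0:
        return 0.0
    tol = r * sdev
    def count(mm):
        total = 0
        for i in range(n - m):          # both lengths use n - m templates
            for j in range(i + 1, n - m):
                if all(abs(x[i + k] - x[j + k]) <= tol for k in range(mm)):
                    total += 1
        return total
    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def _trace(mag_like: np.ndarray, rate=200.0, **kw) -> AccelTrace:
    return AccelTrace(np.column_stack([mag_like, np.zeros_like(mag_like), np.zeros_like(mag_like)]), rate=rate, **kw)


class TestEpoch:
    def test_non_overlapping_count(self):
        trace = _trace(np.zeros(3000))
        assert len(seg.epoch(trace, 500, 0.0)) == 6

    def test_half_overlap_count(self):
        trace = _trace(np.zeros(3000))
        assert len(seg.epoch(trace, 500, 0.5)) == 11

    def test_window_longer_than_trace_gives_no_segments(self):
        trace = _trace(np.zeros(499))
        assert seg.epoch(trace, 500) == []

    @given(n=st.integers(2, 4000), w=st.integers(2, 600))
    @settings(max_examples=60, deadline=None)
    def test_counts_match_closed_form(self, n, w):
        trace = _trace(np.zeros(n))
        assert len(seg.epoch(trace, w, 0.0)) == n // w
        if w % 2 == 0:
            expected = (n - w) // (w // 2) + 1 if n >= w else 0
            assert len(seg.epoch(trace, w, 0.5)) == expected

    def test_reconstruction_of_non_overlapping_epochs(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1234, 3))
        trace = AccelTrace(x, rate=200.0)
        segs = seg.epoch(trace, 300)
        rebuilt = np.concatenate([s.samples for s in segs])
        assert np.array_equal(rebuilt, x[: (1234 // 300) * 300])

    def test_invalid_overlap_rejected(self):
        trace = _trace(np.zeros(100))
        with pytest.raises(ValueError):
            seg.epoch(trace, 10, 0.25)

    def test_odd_window_with_overlap_rejected(self):
        trace = _trace(np.zeros(100))
        with pytest.raises(ValueError):
            seg.epoch(trace, 11, 0.5)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert seg.sample_entropy(np.full(50, 3.3)) == 0.0

    def test_repeating_pattern_matches_oracle_exactly(self):
        x = [1, 2, 3, 1, 2, 3, 1, 2, 3, 1]
        assert seg.sample_entropy(x) == pytest.approx(brute_force_sampen(x), abs=0)

    @pytest.mark.parametrize("n,kind", [(60, "noise"), (200, "noise"), (500, "ar"),
                                        (120, "sine"), (300, "mixed")])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_seeded_series(self, n, kind, seed):
        rng = np.random.default_rng(seed)
        if kind == "noise":
            x = rng.normal(size=n)
        elif kind == "ar":
            x = np.zeros(n)
            for i in range(1, n):
                x[i] = 0.9 * x[i - 1] + rng.normal()
        elif kind == "sine":
            x = np.sin(np.arange(n) * 0.3) + 0.05 * rng.normal(size=n)
        else:
            x = np.concatenate([np.ones(n // 2), rng.normal(size=n - n // 2)])
        got = seg.sample_entropy(x)
        want = brute_force_sampen(x)
        if math.isinf(want):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)

    def test_embedding_dimension_three_matches_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=150)
        p = seg.SampEnParams(m=3, r=0.25)
        assert seg.sample_entropy(x, p) == pytest.approx(
            brute_force_sampen(x, m=3, r=0.25), abs=1e-12
        )

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            seg.sample_entropy([1.0, 2.0, 3.0], seg.SampEnParams(m=2))

    def test_undefined_case_returns_inf(self):
        # identical length-2 templates exist, but their continuations
        # diverge (+5 vs -5): B > 0, A = 0 -> undefined marker
        x = [0.0, 0.1, 5.0, 0.0, 0.1, -5.0, 0.05]
        assert math.isinf(seg.sample_entropy(x))
        assert math.isinf(brute_force_sampen(x))


class TestAlignment:
    def test_fall_window_contains_ground_truth_impact(self, fall_trace):
        trace, impact = fall_trace
        result = seg.locate_fall_window(trace, 500)
        start = result.fall_segment_index * 500
        assert start <= impact * trace.rate < start + 500

    def test_zero_threshold_still_selects_max(self, fall_trace):
        trace, _ = fall_trace
        result = seg.locate_fall_window(trace, 500, threshold=0.0)
        assert result.fall_segment_index == int(np.argmax(result.sampen_values))

    def test_pure_adl_trace_fails_at_calibrated_threshold(self, small_cohort):
        threshold = seg.calibrate_threshold(
            small_cohort.fall_traces()[:20], small_cohort.adl_traces()[:20], 500
        )
        adl = small_cohort.adl_traces()[0]
        with pytest.raises(seg.NoEventFoundError):
            seg.locate_fall_window(adl, 500, threshold=threshold)

    def test_extract_fall_segment_is_aligned_and_labeled(self, fall_trace):
        trace, _ = fall_trace
        segment, result = seg.extract_fall_segment(trace, 500)
        assert segment.label == LABEL_FALL
        assert segment.aligned
        assert segment.start_index == result.fall_segment_index * 500


class TestCalibration:
    def test_two_trace_midpoint_by_hand(self, fall_trace):
        fall, _ = fall_trace
        adl = sd.simulate_adl("walking", 15, 200, seed=3)
        threshold = seg.calibrate_threshold([fall], [adl], 500)
        adl_max = max(seg.window_entropies(adl, 500))
        fall_max = max(seg.window_entropies(fall, 500))
        assert threshold == pytest.approx(0.5 * (adl_max + fall_max))
        assert adl_max < threshold < fall_max

    def test_overlapping_ranges_raise_calibration_error(self, fall_trace):
        fall, _ = fall_trace
        adl = sd.simulate_adl("walking", 15, 200, seed=3)
        # swap the roles: "falls" are ADL traces, so ranges must overlap
        with pytest.raises(seg.CalibrationError) as exc:
            seg.calibrate_threshold([adl], [fall], 500)
        assert exc.value.adl_max >= exc.value.fall_min

    def test_needs_traces_of_both_kinds(self, fall_trace):
        with pytest.raises(ValueError):
            seg.calibrate_threshold([], [fall_trace[0]], 500)


class TestLabelRealworld:
    def _rw_trace(self, impact_s=10.0, rate=100.0, duration=15.0):
        n = int(duration * rate)
        rng = np.random.default_rng(0)
        x = rng.normal(1, 0.05, size=(n, 3))
        return AccelTrace(x, rate=rate, impact_time=impact_s, label_hint=LABEL_FALL)

    def test_fall_segment_spans_expected_samples(self):
        segs = seg.label_realworld(self._rw_trace(impact_s=10.0, rate=100.0))
        fall = [s for s in segs if s.label == LABEL_FALL]
        assert len(fall) == 1
        assert fall[0].start_index == 850
        assert fall[0].start_index + fall[0].length == 1100

    def test_fall_segment_duration_always_2p5_seconds(self):
        for rate in (100.0, 200.0):
            segs = seg.label_realworld(self._rw_trace(rate=rate), window_seconds=2.0)
            fall = [s for s in segs if s.label == LABEL_FALL][0]
            assert fall.length == int(round(2.5 * rate))
            assert fall.aligned

    def test_adl_context_epoched_with_overlap(self):
        segs = seg.label_realworld(self._rw_trace(rate=200.0))
        adl = [s for s in segs if s.label == LABEL_ADL]
        assert len(adl) == 2  # 4 s context, 2.5 s windows, 50% overlap
        assert adl[0].length == 500
        assert adl[1].start_index - adl[0].start_index == 250

    def test_insufficient_pre_impact_data_raises(self):
        with pytest.raises(seg.LabelingError):
            seg.label_realworld(self._rw_trace(impact_s=3.0))

    def test_insufficient_post_impact_data_raises(self):
        with pytest.raises(seg.LabelingError):
            seg.label_realworld(self._rw_trace(impact_s=14.5, duration=15.0))
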