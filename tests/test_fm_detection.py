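"""Movement pipeline: axis fusion, detrend filter, peak detection, matching."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fetaldesk import fm_detection as fmd
from fetaldesk.errors import ConfigError
from fetaldesk.signals import SampleSeries, TriaxialRecord


def record_from_axes(ax, ay, az, fs=500.0):
    n = len(ax)
    return TriaxialRecord(
        t=np.arange(n) / fs, ax=np.asarray(ax, float),
        ay=np.asarray(ay, float), az=np.asarray(az, float), fs=fs,
    )


def brute_force_detrend(x, pole=0.99, scale_T=1.0):
    """Direct recursion oracle: y[n] = p y[n-1] + (x[n] - x[n-1]) / T."""
    y = np.zeros(len(x))
    prev_x = 0.0
    prev_y = 0.0
    for i, xi in enumerate(x):
        y[i] = pole * prev_y + (xi - prev_x) / scale_T
        prev_x, prev_y = xi, y[i]
    return y


class TestFuseAxes:
    def test_pythagorean_triple(self):
        rec = record_from_axes([3.0] * 4, [4.0] * 4, [0.0] * 4)
        assert np.allclose(fmd.fuse_axes(rec).values, 5.0)

    def test_all_zero_record(self):
        rec = record_from_axes([0.0] * 4, [0.0] * 4, [0.0] * 4)
        assert np.all(fmd.fuse_axes(rec).values == 0.0)

    def test_constant_catalogue_means(self):
        # sqrt(11.1521^2 + 10.5529^2 + 16.4638^2), computed directly
        expected = float(np.sqrt(11.1521**2 + 10.5529**2 + 16.4638**2))
        rec = record_from_axes([-11.1521] * 3, [-10.5529] * 3, [-16.4638] * 3)
        assert fmd.fuse_axes(rec).values[0] == pytest.approx(expected)
        assert expected == pytest.approx(22.512, abs=5e-4)

    @given(
        axes=hnp.arrays(
            float, (3, 16),
            elements=st.floats(-10, 10, allow_nan=False, width=32),
        ),
        perm=st.permutations([0, 1, 2]),
        signs=st.tuples(*[st.sampled_from([-1.0, 1.0])] * 3),
    )
    def test_invariant_to_axis_permutation_and_sign(self, axes, perm, signs):
        base = fmd.fuse_axes(record_from_axes(*axes))
        shuffled = [signs[i] * axes[perm[i]] for i in range(3)]
        other = fmd.fuse_axes(record_from_axes(*shuffled))
        assert np.allclose(base.values, other.values, atol=1e-12)


class TestDetrendFilter:
    def test_constant_input_decays_to_zero(self, series_factory):
        c = 5.0
        y = fmd.detrend_filter(series_factory(np.full(3000, c))).values
        # DC gain is exactly 0: the step response decays geometrically
        assert abs(y[2500]) < 1e-6 * abs(c)
        ratios = y[1:100] / y[:99]
        assert np.allclose(ratios, 0.99, atol=1e-9)

    def test_impulse_response_closed_form(self, series_factory):
        x = np.zeros(50)
        x[0] = 1.0
        y = fmd.detrend_filter(series_factory(x)).values
        n = np.arange(1, 50)
        expected = np.r_[1.0, -0.01 * 0.99 ** (n - 1)]
        assert np.allclose(y, expected, atol=1e-12)

    def test_ramp_input_bounded(self, series_factory):
        step = 0.01
        x = step * np.arange(5000)
        y = fmd.detrend_filter(series_factory(x)).values
        # steady-state response to a ramp is step/(1 - pole)
        assert y[-1] == pytest.approx(step / (1 - 0.99), rel=1e-6)
        assert np.all(np.abs(y) <= step / (1 - 0.99) + 1e-9)

    @given(
        x=hnp.arrays(
            float,
            st.integers(2, 400),
            elements=st.floats(-100, 100, allow_nan=False, width=32),
        ),
        pole=st.floats(0.5, 0.999),
        scale_T=st.floats(0.01, 10.0),
    )
    def test_streaming_matches_brute_force_recursion(self, x, pole, scale_T):
        spec = fmd.DetrendFilterSpec(pole=pole, scale_T=scale_T)
        y = fmd.detrend_filter(SampleSeries(x, 500.0), spec).values
        assert np.allclose(y, brute_force_detrend(x, pole, scale_T), atol=1e-9)

    def test_streaming_matches_oracle_on_long_input(self, series_factory):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10_000)
        y = fmd.detrend_filter(series_factory(x)).values
        assert np.max(np.abs(y - brute_force_detrend(x))) < 1e-12 * max(
            1.0, np.max(np.abs(y))
        )

    def test_scale_T_divides_output(self, series_factory):
        x = np.sin(np.arange(500) / 10)
        y1 = fmd.detrend_filter(series_factory(x), fmd.DetrendFilterSpec()).values
        y2 = fmd.detrend_filter(
            series_factory(x), fmd.DetrendFilterSpec(scale_T=2.0)
        ).values
        assert np.allclose(y1, 2.0 * y2, atol=1e-12)

    def test_invalid_pole_rejected(self):
        with pytest.raises(ConfigError):
            fmd.DetrendFilterSpec(pole=1.0)


def burst_series(burst_times, amp=0.01, fs=500.0, duration=30.0, width=0.1):
    """A quiet series with rectangular suprathreshold bursts."""
    n = int(duration * fs)
    x = np.zeros(n)
    for bt in burst_times:
        i = int(bt * fs)
        x[i : i + int(width * fs)] = amp
    return SampleSeries(x, fs, "g")


class TestDetectFm:
    CFG = fmd.PeakDetectorConfig(settle_time=0.0)

    def test_everything_below_threshold(self):
        x = SampleSeries(np.full(5000, 0.001), 500.0, "g")
        assert fmd.detect_fm(x, self.CFG) == []

    def test_two_isolated_bursts_counted_as_two(self):
        x = burst_series([10.0, 20.0])
        events = fmd.detect_fm(x, self.CFG)
        assert fmd.count_fm(events) == 2
        assert events[0].peak_amp == pytest.approx(0.01)
        assert events[0].onset <= events[0].peak_time

    def test_continuous_excursion_is_one_event(self):
        x = SampleSeries(np.full(500, 0.01), 500.0, "g")
        events = fmd.detect_fm(x, fmd.PeakDetectorConfig(settle_time=0.0, min_event_duration=0.0))
        assert len(events) == 1

    def test_bursts_within_gap_merge(self):
        x = burst_series([10.0, 10.5])  # 0.5 s apart < 1 s merge gap
        assert len(fmd.detect_fm(x, self.CFG)) == 1

    def test_negative_excursions_detected_via_rectification(self):
        x = burst_series([10.0], amp=-0.01)
        events = fmd.detect_fm(x, self.CFG)
        assert len(events) == 1
        assert events[0].peak_amp == pytest.approx(0.01)

    def test_settle_time_suppresses_warmup_transient(self):
        x = burst_series([0.5, 10.0])
        events = fmd.detect_fm(x, fmd.PeakDetectorConfig(settle_time=2.0))
        assert len(events) == 1
        assert events[0].onset == pytest.approx(10.0)

    def test_short_noise_spikes_rejected_by_duration(self):
        x = np.zeros(5000)
        x[1000] = 0.01  # single-sample spike
        events = fmd.detect_fm(SampleSeries(x, 500.0, "g"),
                               fmd.PeakDetectorConfig(settle_time=0.0))
        assert events == []

    @given(st.floats(0.001, 0.05), st.floats(0.001, 0.05))
    def test_suprathreshold_time_monotone_in_threshold(self, thr_lo, thr_hi):
        # the literal detection criterion — time spent above threshold — is
        # monotone; the grouped event count need not be, since a higher
        # threshold can split one broad excursion into several narrow ones
        lo, hi = sorted([thr_lo, thr_hi])
        rng = np.random.default_rng(5)
        x = SampleSeries(rng.normal(0, 0.01, 4000), 500.0, "g")

        def above_time(thr):
            events = fmd.detect_fm(x, fmd.PeakDetectorConfig(
                threshold=thr, settle_time=0.0, min_event_duration=0.0,
                min_event_gap=0.0))
            return int(np.sum(np.abs(x.values) > thr)), len(events)

        samples_lo, n_lo = above_time(lo)
        samples_hi, n_hi = above_time(hi)
        assert samples_hi <= samples_lo
        if n_lo == 0:
            assert n_hi == 0  # nothing above a lower bar, nothing above a higher

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ConfigError):
            fmd.PeakDetectorConfig(threshold=0.0)


class TestCompareWithMp:
    def ev(self, t):
        return fmd.MovementEvent(onset=t - 0.05, peak_time=t, peak_amp=0.01)

    def test_single_match_within_window(self):
        r = fmd.compare_with_mp([self.ev(10.0)], [10.5], match_window=2.0)
        assert (r.matched, r.false_negatives) == (1, 0)

    def test_algorithm_counts_twice_maternal_perception(self):
        r = fmd.compare_with_mp([self.ev(10.0), self.ev(20.0)], [10.2])
        assert r.fm_count == 2
        assert r.mp_count == 1
        assert r.false_negatives == 0

    def test_unmatched_marker_is_false_negative(self):
        r = fmd.compare_with_mp([], [10.0])
        assert r.false_negatives == 1

    def test_matching_is_one_to_one(self):
        r = fmd.compare_with_mp([self.ev(10.0)], [9.5, 10.5], match_window=2.0)
        assert r.matched == 1
        assert r.false_negatives == 1

    def test_negative_window_rejected(self):
        with pytest.raises(ConfigError):
            fmd.compare_with_mp([], [], match_window=-1.0)
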