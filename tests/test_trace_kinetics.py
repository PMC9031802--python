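import numpy as np
import pytest

from cardioflow import trace_kinetics as tk
from cardioflow.video_io import TimeSeries

from oracles import (
    literal_pairing,
    literal_peak_rules,
    percentile_linear,
    random_piecewise_linear_trace,
)


def triangle(up=10, down=10, height=100.0):
    """Symmetric-ish triangle rising over ``up`` samples, falling over
    ``down``."""
    rise = np.linspace(0, height, up + 1)
    fall = np.linspace(height, 0, down + 1)[1:]
    return np.concatenate([rise, fall])


class TestBaseline:
    def test_constant_trace(self):
        assert tk.baseline(np.full(20, 7.0), 10) == 7.0
        assert tk.baseline(np.full(20, 7.0), 90) == 7.0

    def test_uniform_grid_closed_form(self):
        values = np.arange(101.0)  # 0..100 inclusive
        assert tk.baseline(values, 10) == pytest.approx(10.0)

    def test_interpolation_convention(self):
        values = np.array([0.0] * 9 + [100.0])
        assert tk.baseline(values, 10) == pytest.approx(0.0)

    def test_matches_longhand_percentile(self, rng):
        for _ in range(50):
            values = rng.uniform(-10, 10, size=rng.integers(1, 60))
            p = rng.uniform(0, 100)
            assert tk.baseline(values, p) == pytest.approx(
                percentile_linear(values, p), rel=1e-12, abs=1e-12
            )

    def test_accepts_time_series(self):
        series = TimeSeries(values=np.arange(101.0), dt=0.02)
        assert tk.baseline(series, 10) == pytest.approx(10.0)


class TestDetectPeaks:
    def test_flat_trace_no_peaks(self):
        assert tk.detect_peaks(np.full(50, 3.0), baseline=3.0) == []

    def test_five_percent_rule(self):
        # large triangular peak (amplitude 100) plus a small bump (4)
        trace = np.concatenate(
            [triangle(10, 10, 100.0), np.zeros(5), triangle(3, 3, 4.0), [0.0]]
        )
        peaks = tk.detect_peaks(trace, baseline=0.0)
        assert len(peaks) == 1
        assert peaks[0].amplitude == pytest.approx(100.0)

    def test_five_percent_rule_keeps_borderline(self):
        trace = np.concatenate(
            [triangle(10, 10, 100.0), np.zeros(5), triangle(3, 3, 6.0), [0.0]]
        )
        assert len(tk.detect_peaks(trace, baseline=0.0)) == 2

    def test_triangle_endpoints(self):
        # rise 0->100 over samples 0..10, fall back over 10..20; the 20%
        # level (20.0) is crossed exactly at samples 2 and 18
        trace = triangle(10, 10, 100.0)
        peaks = tk.detect_peaks(trace, baseline=0.0, endpoint_frac=0.2)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start_idx, p.apex_idx, p.end_idx) == (2, 10, 18)

    def test_plateau_takes_centre(self):
        trace = np.array([0, 1, 5, 5, 5, 1, 0], dtype=float)
        peaks = tk.detect_peaks(trace, baseline=0.0)
        assert peaks[0].apex_idx == 3

    def test_even_plateau_takes_left_centre(self):
        trace = np.array([0, 1, 5, 5, 1, 0], dtype=float)
        peaks = tk.detect_peaks(trace, baseline=0.0)
        assert peaks[0].apex_idx == 2

    def test_boundary_peak_truncated_and_flagged(self):
        trace = np.concatenate([[80.0], np.linspace(100, 0, 21)])
        peaks = tk.detect_peaks(trace, baseline=0.0)
        assert len(peaks) == 1
        assert peaks[0].truncated_left
        assert peaks[0].start_idx == 0

    def test_endpoints_bracket_apex_and_sit_near_level(self, rng):
        for _ in range(30):
            trace = random_piecewise_linear_trace(rng)
            base = tk.baseline(trace, 10)
            for p in tk.detect_peaks(trace, baseline=base):
                assert p.start_idx <= p.apex_idx <= p.end_idx
                level = base + 0.2 * p.amplitude
                for idx, trunc in (
                    (p.start_idx, p.truncated_left),
                    (p.end_idx, p.truncated_right),
                ):
                    if not trunc:
                        neighbors = trace[
                            max(0, idx - 1): min(trace.size, idx + 2)
                        ]
                        span = np.abs(np.diff(neighbors)).max() if len(
                            neighbors
                        ) > 1 else 0.0
                        assert abs(trace[idx] - level) <= span + 1e-9

    def test_shift_invariance(self, rng):
        trace = random_piecewise_linear_trace(rng)
        base = tk.baseline(trace, 10)
        ref = tk.detect_peaks(trace, baseline=base)
        shifted = tk.detect_peaks(trace + 37.5, baseline=base + 37.5)
        assert [(p.start_idx, p.apex_idx, p.end_idx) for p in ref] == [
            (p.start_idx, p.apex_idx, p.end_idx) for p in shifted
        ]

    def test_scale_invariance_of_timings(self, rng):
        trace = random_piecewise_linear_trace(rng)
        base = tk.baseline(trace, 10)
        ref = tk.detect_peaks(trace, baseline=base)
        scaled = tk.detect_peaks(3.0 * trace, baseline=3.0 * base)
        assert [(p.start_idx, p.apex_idx, p.end_idx) for p in ref] == [
            (p.start_idx, p.apex_idx, p.end_idx) for p in scaled
        ]
        for a, b in zip(ref, scaled):
            assert b.amplitude == pytest.approx(3.0 * a.amplitude)

    def test_agrees_with_literal_oracle(self, rng):
        for _ in range(200):
            trace = random_piecewise_linear_trace(rng)
            base, expected = literal_peak_rules(trace)
            got = tk.detect_peaks(trace, baseline=tk.baseline(trace, 10))
            assert [(p.start_idx, p.apex_idx, p.end_idx) for p in got] == expected


class TestPairEvents:
    dt = 0.02

    def _peaks_from(self, trace):
        return tk.detect_peaks(trace, baseline=0.0)

    def test_single_peak_unmatched(self):
        trace = np.concatenate([triangle(), [0.0] * 5])
        peaks = self._peaks_from(trace)
        events, unmatched = tk.pair_events(trace, peaks, 0.1, self.dt)
        assert events == []
        assert len(unmatched) == 1

    def test_two_close_peaks_pair_with_delay(self):
        # contraction end and relaxation start separated by one sample
        trace = np.concatenate([triangle(5, 5), [0.0], triangle(5, 5), [0.0]])
        peaks = self._peaks_from(trace)
        assert len(peaks) == 2
        gap_samples = peaks[1].start_idx - peaks[0].end_idx
        events, unmatched = tk.pair_events(trace, peaks, 0.1, self.dt)
        assert len(events) == 1 and unmatched == []
        assert events[0].delay_s == pytest.approx(gap_samples * self.dt)

    def test_three_peaks_greedy(self):
        gap_small = [0.0]  # ~1 sample gap
        gap_large = [0.0] * 30  # 30 samples = 0.6 s >> max gap
        trace = np.concatenate(
            [triangle(5, 5), gap_small, triangle(5, 5), gap_large,
             triangle(5, 5), [0.0]]
        )
        peaks = self._peaks_from(trace)
        assert len(peaks) == 3
        events, unmatched = tk.pair_events(trace, peaks, 0.1, self.dt)
        assert len(events) == 1
        assert len(unmatched) == 1
        assert unmatched[0].apex_idx == peaks[2].apex_idx

    def test_agrees_with_literal_pairing(self, rng):
        for _ in range(100):
            trace = random_piecewise_linear_trace(rng)
            base, triples = literal_peak_rules(trace)
            expected_events, expected_unmatched = literal_pairing(
                triples, 0.1, self.dt
            )
            peaks = tk.detect_peaks(trace, baseline=tk.baseline(trace, 10))
            events, unmatched = tk.pair_events(trace, peaks, 0.1, self.dt)
            got_events = [
                (
                    (e.contraction.start_idx, e.contraction.apex_idx,
                     e.contraction.end_idx),
                    (e.relaxation.start_idx, e.relaxation.apex_idx,
                     e.relaxation.end_idx),
                )
                for e in events
            ]
            assert got_events == expected_events
            assert [
                (p.start_idx, p.apex_idx, p.end_idx) for p in unmatched
            ] == expected_unmatched

    def test_dfdt_max_on_rising_edge(self):
        trace = np.array([0, 10, 50, 60, 100, 40, 10, 0, 0, 10, 60, 100, 50, 10, 0],
                         dtype=float)
        peaks = self._peaks_from(trace)
        events, _ = tk.pair_events(trace, peaks, max_gap_s=0.2, dt=self.dt)
        assert len(events) == 1
        c = events[0].contraction
        seg = np.diff(trace[c.start_idx: c.apex_idx + 1])
        assert events[0].dfdt_max == pytest.approx(seg.max() / self.dt)


class TestSummarize:
    def _event(self, **overrides):
        peak = tk.Peak(start_idx=0, apex_idx=2, end_idx=4, amplitude=1.0,
                       baseline=0.0)
        base = dict(
            contraction=peak, relaxation=peak, delay_s=0.02,
            contraction_time_s=0.1, relaxation_time_s=0.12, ttp_s=0.1,
            dfdt_max=5.0,
        )
        base.update(overrides)
        return tk.ContractionEvent(**base)

    def test_beat_rate(self):
        events = [self._event() for _ in range(4)]
        summary = tk.summarize_kinetics(events, duration_s=2.0)
        assert summary.beat_rate_hz == pytest.approx(2.0)
        assert summary.n_events == 4

    def test_equal_values_zero_sem(self):
        events = [self._event(ttp_s=0.1), self._event(ttp_s=0.1)]
        summary = tk.summarize_kinetics(events, duration_s=1.0)
        assert summary.mean["ttp_s"] == pytest.approx(0.1)
        assert summary.sem["ttp_s"] == pytest.approx(0.0)

    def test_sem_hand_computed(self):
        events = [self._event(ttp_s=t) for t in (0.1, 0.2, 0.3)]
        summary = tk.summarize_kinetics(events, duration_s=1.0)
        assert summary.mean["ttp_s"] == pytest.approx(0.2)
        # sample SD 0.1 / sqrt(3)
        assert summary.sem["ttp_s"] == pytest.approx(0.05773502, abs=1e-6)

    def test_single_event_no_sem(self):
        summary = tk.summarize_kinetics([self._event()], duration_s=1.0)
        assert summary.mean
        assert summary.sem == {}

    def test_empty_events(self):
        summary = tk.summarize_kinetics([], duration_s=2.0)
        assert summary.n_events == 0
        assert summary.beat_rate_hz == 0.0
        assert summary.mean == {} and summary.sem == {}

    def test_periodic_trace_exact_beat_rate(self):
        # 5 double-peaked beats of period 1 s at dt = 0.02 s
        dt, period, n_beats = 0.02, 1.0, 5
        beat = np.concatenate(
            [triangle(4, 4, 100.0), [0.0], triangle(4, 4, 80.0),
             np.zeros(int(period / dt) - 19)]
        )
        trace = np.tile(beat, n_beats)
        base = tk.baseline(trace, 10)
        peaks = tk.detect_peaks(trace, baseline=base)
        events, _ = tk.pair_events(trace, peaks, max_gap_s=0.1, dt=dt)
        summary = tk.summarize_kinetics(events, duration_s=trace.size * dt)
        assert summary.n_events == n_beats
        assert summary.beat_rate_hz == pytest.approx(1.0 / period)
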