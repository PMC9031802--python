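"""Velocity-trace signal processing: baseline, peak detection, pairing of
peaks into contraction/relaxation events, and kinetic summaries.

Rules, in order: (1) peaks below 5% of the largest peak amplitude above
baseline are discarded; (2) the baseline is the 10th percentile of the
trace; (3) consecutive peaks whose endpoints nearly touch pair into a
contraction-followed-by-relaxation event; (4) peak start/end points sit
20% above baseline on each side of the apex; (5) the delay is the interval
between the first peak's end and the second peak's start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cardioflow.video_io import TimeSeries

__all__ = [
    "Peak",
    "ContractionEvent",
    "KineticsSummary",
    "baseline",
    "detect_peaks",
    "pair_events",
    "summarize_kinetics",
    "rising_edge_max_slope",
]

EVENT_METRICS = (
    "ttp_s",
    "dfdt_max",
    "contraction_time_s",
    "relaxation_time_s",
    "delay_s",
)


@dataclass
class Peak:
    """A single peak with interpolated 20%-level endpoints.

    ``truncated_left``/``truncated_right`` flag endpoints clipped at the
    trace boundary or a neighbouring apex because the trace never fell back
    to the endpoint level.
    """

    start_idx: int
    apex_idx: int
    end_idx: int
    amplitude: float
    baseline: float
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self) -> None:
        if not self.start_idx <= self.apex_idx <= self.end_idx:
            raise ValueError(
                f"peak indices out of order: {self.start_idx}, "
                f"{self.apex_idx}, {self.end_idx}"
            )
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")


@dataclass
class ContractionEvent:
    """A contraction peak followed by a relaxation peak."""

    contraction: Peak
    relaxation: Peak
    delay_s: float
    contraction_time_s: float
    relaxation_time_s: float
    ttp_s: float
    dfdt_max: float


@dataclass
class KineticsSummary:
    n_events: int
    beat_rate_hz: float
    mean: dict = field(default_factory=dict)
    sem: dict = field(default_factory=dict)


def baseline(trace: TimeSeries | np.ndarray, percentile: float = 10.0) -> float:
    """Linear-interpolation percentile of the trace values."""
    values = trace.values if isinstance(trace, TimeSeries) else np.asarray(trace)
    if values.size == 0:
        raise ValueError("empty trace")
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    return float(np.percentile(values, percentile))


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus report their centre sample
    (left-of-centre on even plateaus). Boundary samples never qualify."""
    n = values.size
    maxima = []
    i = 1
    while i < n - 1:
        if values[i] <= values[i - 1]:
            i += 1
            continue
        j = i
        while j < n - 1 and values[j + 1] == values[i]:
            j += 1
        if j < n - 1 and values[j + 1] < values[i]:
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def _find_endpoint(
    values: np.ndarray, apex: int, level: float, limit: int, step: int
) -> tuple[int, bool]:
    """Scan outward from the apex for the first crossing of ``level``.

    Returns (index, truncated). The fractional crossing position between
    the last above-level sample and the first at-or-below one is rounded to
    the nearest sample. ``limit`` is the last admissible index (trace
    boundary or neighbouring apex).
    """
    j = apex
    while j != limit:
        nxt = j + step
        if values[nxt] <= level:
            if values[nxt] == values[j]:
                frac = float(nxt)
            else:
                frac = j + step * (values[j] - level) / (values[j] - values[nxt])
            return int(round(frac)), False
        j = nxt
    return limit, True


def detect_peaks(
    trace: TimeSeries | np.ndarray,
    baseline: float,
    min_rel_amplitude: float = 0.05,
    endpoint_frac: float = 0.20,
) -> list[Peak]:
    """Detect peaks above the baseline and place their endpoints.

    Local maxima above the baseline are candidates; those with amplitude
    below ``min_rel_amplitude`` of the largest candidate amplitude are
    discarded. Each surviving peak's start/end are the nearest samples on
    either side where the trace first falls to
    ``baseline + endpoint_frac * amplitude``.
    """
    if not 0 < min_rel_amplitude < 1:
        raise ValueError("min_rel_amplitude must be in (0, 1)")
    if not 0 < endpoint_frac < 1:
        raise ValueError("endpoint_frac must be in (0, 1)")
    values = trace.values if isinstance(trace, TimeSeries) else np.asarray(
        trace, dtype=np.float64
    )
    candidates = [
        i for i in _local_maxima(values) if values[i] > baseline
    ]
    if not candidates:
        return []
    amps = values[candidates] - baseline
    threshold = min_rel_amplitude * amps.max()
    kept = [i for i, a in zip(candidates, amps) if a >= threshold]

    peaks: list[Peak] = []
    for pos, apex in enumerate(kept):
        amp = float(values[apex] - baseline)
        level = baseline + endpoint_frac * amp
        left_limit = kept[pos - 1] if pos > 0 else 0
        right_limit = kept[pos + 1] if pos < len(kept) - 1 else values.size - 1
        start, trunc_l = _find_endpoint(values, apex, level, left_limit, -1)
        end, trunc_r = _find_endpoint(values, apex, level, right_limit, +1)
        peaks.append(
            Peak(
                start_idx=start,
                apex_idx=apex,
                end_idx=end,
                amplitude=amp,
                baseline=float(baseline),
                truncated_left=trunc_l,
                truncated_right=trunc_r,
            )
        )
    return peaks


def rising_edge_max_slope(
    values: np.ndarray, peak: Peak, dt: float
) -> float:
    """Largest single-interval rise on the peak's rising edge, per second."""
    if peak.apex_idx == peak.start_idx:
        return 0.0
    seg = values[peak.start_idx : peak.apex_idx + 1]
    return float(np.diff(seg).max() / dt)


def pair_events(
    values: np.ndarray,
    peaks: list[Peak],
    max_gap_s: float = 0.1,
    dt: float = 0.02,
) -> tuple[list[ContractionEvent], list[Peak]]:
    """Greedy left-to-right pairing of peaks into contraction/relaxation
    events.

    Peak i and i+1 pair when the gap from i's end to (i+1)'s start is at
    most ``max_gap_s`` (and non-negative); matched peaks are consumed.
    Returns ``(events, unmatched_peaks)``.
    """
    values = np.asarray(values, dtype=np.float64)
    events: list[ContractionEvent] = []
    unmatched: list[Peak] = []
    i = 0
    while i < len(peaks):
        if i + 1 < len(peaks):
            gap = (peaks[i + 1].start_idx - peaks[i].end_idx) * dt
            if 0 <= gap <= max_gap_s:
                c, r = peaks[i], peaks[i + 1]
                events.append(
                    ContractionEvent(
                        contraction=c,
                        relaxation=r,
                        delay_s=gap,
                        contraction_time_s=(c.end_idx - c.start_idx) * dt,
                        relaxation_time_s=(r.end_idx - r.start_idx) * dt,
                        ttp_s=(c.apex_idx - c.start_idx) * dt,
                        dfdt_max=rising_edge_max_slope(values, c, dt),
                    )
                )
                i += 2
                continue
        unmatched.append(peaks[i])
        i += 1
    return events, unmatched


def summarize_kinetics(
    events: list[ContractionEvent], duration_s: float
) -> KineticsSummary:
    """Beat rate plus mean and SEM (sample SD / sqrt(n)) of event metrics.

    SEM entries are omitted when fewer than two events exist; metric means
    are omitted entirely for an empty event list.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    n = len(events)
    summary = KineticsSummary(n_events=n, beat_rate_hz=n / duration_s)
    if n == 0:
        return summary
    for name in EVENT_METRICS:
        vals = np.array([getattr(e, name) for e in events], dtype=np.float64)
        summary.mean[name] = float(vals.mean())
        if n >= 2:
            summary.sem[name] = float(vals.std(ddof=1) / np.sqrt(n))
    return summary
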