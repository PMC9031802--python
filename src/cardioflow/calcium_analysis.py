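"""Ca2+ branch: background subtraction, normalized mean green intensity,
frame-difference spark series, and per-transient kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cardioflow.video_io import VideoStack, TimeSeries
from cardioflow import trace_kinetics

__all__ = [
    "CalciumTrace",
    "SparkSeries",
    "TransientMetrics",
    "subtract_background",
    "intensity_trace",
    "spark_series",
    "transient_metrics",
]

SPARK_THRESHOLD = 10.0
WIDTH_HEIGHT_FRAC = 0.10
BASELINE_PERCENTILE = 10.0


@dataclass
class CalciumTrace(TimeSeries):
    """Per-frame mean green intensity (zero pixels excluded), rescaled so
    the recording maximum is 255; ``normalized`` is False for an all-zero
    recording where rescaling was skipped."""

    baseline: float = 0.0
    normalized: bool = True
    # multiplier applied by the max-255 rescale; divide by it to get back to
    # the acquisition intensity scale (slopes must be compared across
    # recordings on that scale, where the rescale would cancel real
    # amplitude differences)
    norm_scale: float = 1.0


@dataclass
class SparkSeries:
    """Per-frame-pair spark aggregates from thresholded frame differences.

    ``sp_intensity`` is the mean of super-threshold positive differences
    (series rescaled to a 255 maximum); ``sp_area`` the fraction of image
    area those pixels occupy.
    """

    sp_intensity: np.ndarray
    sp_area: np.ndarray
    threshold: float
    dt: float
    normalized: bool = True

    def __post_init__(self) -> None:
        self.sp_intensity = np.asarray(self.sp_intensity, dtype=np.float64)
        self.sp_area = np.asarray(self.sp_area, dtype=np.float64)
        if self.sp_intensity.shape != self.sp_area.shape:
            raise ValueError("sp_intensity and sp_area must align")
        if ((self.sp_area < 0) | (self.sp_area > 1)).any():
            raise ValueError("sp_area must lie in [0, 1]")


@dataclass
class TransientMetrics:
    """Kinetics of one Ca2+ transient.

    ``t90_s`` is None (and ``truncated`` True) when the signal never
    returns to 10% of the amplitude before the next transient or the end
    of the trace.
    """

    t0_s: float
    ttp_s: float
    t90_s: float | None
    amplitude: float
    width10_s: float | None
    dfdt_max: float
    spark_count_before: int
    truncated: bool = False
    peak: trace_kinetics.Peak | None = None


def subtract_background(
    stack: VideoStack, method: str = "temporal_min", percentile: float = 10.0
) -> VideoStack:
    """Subtract a static per-pixel background; negatives clamp to 0.

    ``temporal_min`` (default) subtracts each pixel's temporal minimum —
    exact for an additive static background and idempotent. ``percentile``
    subtracts a per-pixel temporal percentile instead.
    """
    if method == "temporal_min":
        bg = stack.frames.min(axis=0)
    elif method == "percentile":
        bg = np.percentile(stack.frames, percentile, axis=0)
    else:
        raise ValueError(f"unknown background method {method!r}")
    frames = np.clip(stack.frames - bg, 0.0, None)
    return VideoStack(frames=frames, fps=stack.fps, channel=stack.channel)


def intensity_trace(
    stack: VideoStack, baseline_percentile: float = BASELINE_PERCENTILE
) -> CalciumTrace:
    """Mean intensity per frame over nonzero pixels, rescaled to max 255.

    Frames with no nonzero pixel contribute 0. An all-zero recording is
    returned unscaled with ``normalized=False``.
    """
    frames = stack.frames
    nonzero = frames > 0
    counts = nonzero.sum(axis=(1, 2))
    sums = np.where(nonzero, frames, 0.0).sum(axis=(1, 2))
    means = np.divide(
        sums, counts, out=np.zeros(len(frames)), where=counts > 0
    )
    peak = means.max()
    normalized = peak > 0
    scale = 1.0
    if normalized:
        scale = 255.0 / peak
        means = means * scale
    else:
        warnings.warn("all-zero recording; intensity normalization skipped")
    return CalciumTrace(
        values=means,
        dt=stack.dt,
        baseline=float(np.percentile(means, baseline_percentile)),
        normalized=normalized,
        norm_scale=scale,
    )


def spark_series(
    stack: VideoStack, threshold: float = SPARK_THRESHOLD
) -> SparkSeries:
    """Thresholded positive frame differences aggregated per frame pair.

    Only intensity rises count; the threshold (inclusive, default 10) is
    applied to raw 8-bit-scale differences before the series-level rescale
    of ``sp_intensity`` to a 255 maximum.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    diffs = np.clip(stack.frames[1:] - stack.frames[:-1], 0.0, None)
    mask = diffs >= threshold
    npix = stack.height * stack.width
    counts = mask.sum(axis=(1, 2))
    area = counts / npix
    sums = np.where(mask, diffs, 0.0).sum(axis=(1, 2))
    intensity = np.divide(
        sums, counts, out=np.zeros(len(diffs)), where=counts > 0
    )
    peak = intensity.max() if intensity.size else 0.0
    normalized = peak > 0
    if normalized:
        intensity = intensity * (255.0 / peak)
    else:
        warnings.warn("no super-threshold differences; spark normalization skipped")
    return SparkSeries(
        sp_intensity=intensity,
        sp_area=area,
        threshold=float(threshold),
        dt=stack.dt,
        normalized=normalized,
    )


def _spark_peak_indices(
    sparks: SparkSeries, min_rel_amplitude: float
) -> list[int]:
    peaks = trace_kinetics.detect_peaks(
        sparks.sp_intensity,
        baseline=0.0,
        min_rel_amplitude=min_rel_amplitude,
        endpoint_frac=0.5,  # endpoints unused for counting
    )
    return [p.apex_idx for p in peaks]


def transient_metrics(
    trace: CalciumTrace,
    sparks: SparkSeries | None = None,
    min_rel_amplitude: float = 0.05,
    width_height_frac: float = WIDTH_HEIGHT_FRAC,
    spark_min_rel_amplitude: float = 0.05,
) -> list[TransientMetrics]:
    """Per-transient kinetics from a normalized intensity trace.

    Peaks are detected with endpoints at 10% height above baseline; per
    peak: t0 is the start crossing, TTP the start-to-apex time, width the
    start-to-end time, T90 the apex-to-end (falling 10%-crossing) time and
    (dF/dT)max the largest forward difference on the rising edge divided by
    dt. Spark peaks in ``sparks.sp_intensity`` strictly between the
    previous transient's end (or the series start) and t0 are counted.

    ``dfdt_max`` is reported on the acquisition intensity scale (the
    max-255 trace rescale is undone) so it stays comparable across
    recordings; all timings and the amplitude refer to the normalized
    trace.
    """
    if trace.values.size < 3:
        raise ValueError("trace too short for transient analysis")
    peaks = trace_kinetics.detect_peaks(
        trace,
        baseline=trace.baseline,
        min_rel_amplitude=min_rel_amplitude,
        endpoint_frac=width_height_frac,
    )
    spark_apexes = (
        _spark_peak_indices(sparks, spark_min_rel_amplitude)
        if sparks is not None and sparks.sp_intensity.size >= 3
        else []
    )
    out: list[TransientMetrics] = []
    prev_end = -1
    for p in peaks:
        dt = trace.dt
        truncated = p.truncated_right
        t90 = None if truncated else (p.end_idx - p.apex_idx) * dt
        width = None if (p.truncated_left or truncated) else (
            (p.end_idx - p.start_idx) * dt
        )
        n_sparks = sum(prev_end < k < p.start_idx for k in spark_apexes)
        out.append(
            TransientMetrics(
                t0_s=p.start_idx * dt,
                ttp_s=(p.apex_idx - p.start_idx) * dt,
                t90_s=t90,
                amplitude=p.amplitude,
                width10_s=width,
                dfdt_max=trace_kinetics.rising_edge_max_slope(
                    trace.values, p, dt
                ) / trace.norm_scale,
                spark_count_before=n_sparks,
                truncated=p.truncated_left or truncated,
                peak=p,
            )
        )
        prev_end = p.end_idx
    return out
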