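"""End-to-end analysis pipelines tying the modules together.

``analyze_contraction`` runs optical flow -> velocity trace -> peak
pairing; ``analyze_calcium`` runs background subtraction -> intensity and
spark series -> transient metrics. Both return plain dictionaries that the
CLI serializes to CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cardioflow import calcium_analysis, optical_flow, trace_kinetics
from cardioflow.config import DEFAULTS, dump_config
from cardioflow.video_io import VideoStack, TimeSeries

__all__ = [
    "analyze_contraction",
    "analyze_calcium",
    "events_to_frame",
    "transients_to_frame",
    "write_contraction_results",
    "write_calcium_results",
]

EVENT_COLUMNS = [
    "start_s", "apex_s", "end_s", "ttp_s", "dfdt_max",
    "contraction_time_s", "delay_s", "relaxation_time_s",
]
TRANSIENT_COLUMNS = [
    "t0_s", "ttp_s", "t90_s", "amplitude", "width10_s", "dfdt_max",
    "spark_count_before",
]


def analyze_contraction(stack: VideoStack, config: dict | None = None) -> dict:
    """Full contraction-velocity pipeline on one video."""
    cfg = config or DEFAULTS
    flow_cfg, peak_cfg = cfg["flow"], cfg["peaks"]
    trace = optical_flow.velocity_trace(
        stack,
        alpha=flow_cfg["alpha"],
        n_iter=flow_cfg["iterations"],
        tol=flow_cfg["tolerance"],
        fraction=flow_cfg["fraction"],
        reduce=flow_cfg["reduce"],
    )
    return analyze_velocity_series(trace, cfg, duration_s=stack.duration_s)


def analyze_velocity_series(
    trace: TimeSeries, config: dict | None = None, duration_s: float | None = None
) -> dict:
    """Peak pipeline on an existing velocity trace (trace-only analysis)."""
    cfg = config or DEFAULTS
    peak_cfg = cfg["peaks"]
    base = trace_kinetics.baseline(trace, peak_cfg["baseline_percentile"])
    peaks = trace_kinetics.detect_peaks(
        trace,
        baseline=base,
        min_rel_amplitude=peak_cfg["min_rel_amplitude"],
        endpoint_frac=peak_cfg["endpoint_frac"],
    )
    events, unmatched = trace_kinetics.pair_events(
        trace.values, peaks, max_gap_s=peak_cfg["max_gap_s"], dt=trace.dt
    )
    duration = duration_s if duration_s is not None else trace.duration_s
    summary = trace_kinetics.summarize_kinetics(events, duration)
    return dict(
        trace=trace,
        baseline=base,
        peaks=peaks,
        events=events,
        unmatched=unmatched,
        summary=summary,
    )


def analyze_calcium(stack: VideoStack, config: dict | None = None) -> dict:
    """Full Ca2+ pipeline on one (green-channel) video."""
    cfg = config or DEFAULTS
    cal_cfg = cfg["calcium"]
    background = cal_cfg.get("background", "temporal_min")
    if isinstance(background, str) and background.startswith("percentile:"):
        sub = calcium_analysis.subtract_background(
            stack, method="percentile",
            percentile=float(background.split(":", 1)[1]),
        )
    else:
        sub = calcium_analysis.subtract_background(stack, method=background)
    trace = calcium_analysis.intensity_trace(
        sub, baseline_percentile=cal_cfg["baseline_percentile"]
    )
    sparks = calcium_analysis.spark_series(
        sub, threshold=cal_cfg["spark_threshold"]
    )
    transients = calcium_analysis.transient_metrics(
        trace,
        sparks,
        min_rel_amplitude=cfg["peaks"]["min_rel_amplitude"],
        width_height_frac=cal_cfg["width_height_frac"],
    )
    return dict(
        trace=trace,
        sparks=sparks,
        transients=transients,
        beat_rate_hz=len(transients) / stack.duration_s,
        duration_s=stack.duration_s,
    )


def events_to_frame(result: dict) -> pd.DataFrame:
    dt = result["trace"].dt
    rows = []
    for e in result["events"]:
        rows.append(
            dict(
                start_s=e.contraction.start_idx * dt,
                apex_s=e.contraction.apex_idx * dt,
                end_s=e.relaxation.end_idx * dt,
                ttp_s=e.ttp_s,
                dfdt_max=e.dfdt_max,
                contraction_time_s=e.contraction_time_s,
                delay_s=e.delay_s,
                relaxation_time_s=e.relaxation_time_s,
            )
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def transients_to_frame(result: dict) -> pd.DataFrame:
    rows = [
        {k: getattr(tr, k) for k in TRANSIENT_COLUMNS}
        for tr in result["transients"]
    ]
    return pd.DataFrame(rows, columns=TRANSIENT_COLUMNS)


def _summary_json(summary) -> dict:
    return dict(
        n_events=summary.n_events,
        beat_rate_hz=summary.beat_rate_hz,
        mean=summary.mean,
        sem=summary.sem,
    )


def write_contraction_results(result: dict, out_dir, stem: str, config: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace = result["trace"]
    pd.DataFrame(
        {"time_s": trace.times, "velocity_px_per_s": trace.values}
    ).to_csv(out / f"{stem}_velocity.csv", index=False)
    events_to_frame(result).to_csv(out / f"{stem}_events.csv", index=False)
    with open(out / f"{stem}_summary.json", "w", encoding="utf-8") as fh:
        json.dump(_summary_json(result["summary"]), fh, indent=2)
    dump_config(config, out / f"{stem}_config.yaml")


def write_calcium_results(result: dict, out_dir, stem: str, config: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace, sparks = result["trace"], result["sparks"]
    pd.DataFrame(
        {"time_s": trace.times, "intensity": trace.values}
    ).to_csv(out / f"{stem}_intensity.csv", index=False)
    pd.DataFrame(
        {
            "time_s": np.arange(sparks.sp_intensity.size) * sparks.dt,
            "sp_intensity": sparks.sp_intensity,
            "sp_area": sparks.sp_area,
        }
    ).to_csv(out / f"{stem}_sparks.csv", index=False)
    transients_to_frame(result).to_csv(
        out / f"{stem}_transients.csv", index=False
    )
    metrics = transients_to_frame(result)
    summary = dict(
        n_transients=len(result["transients"]),
        beat_rate_hz=result["beat_rate_hz"],
        mean={
            c: (float(metrics[c].mean()) if metrics[c].notna().any() else None)
            for c in TRANSIENT_COLUMNS
            if len(metrics)
        },
    )
    with open(out / f"{stem}_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    dump_config(config, out / f"{stem}_config.yaml")
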