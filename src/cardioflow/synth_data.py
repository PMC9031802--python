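"""Synthetic video generation with recorded ground truth.

Two families of recordings are emulated: a striped sarcomere-like texture
undergoing periodic contraction/relaxation displacement, and a diffuse
green fluorescence cell whose brightness follows a double-exponential Ca2+
transient train with brief localized sparks. Every generated stack comes
with a manifest holding the parameters and independently computed truth
values (timing truths come from bisection on the continuous noiseless
waveform, never from the analysis code).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from cardioflow.video_io import VideoStack

__all__ = [
    "SynthManifest",
    "make_contraction_video",
    "make_calcium_video",
    "make_group_pair",
    "regenerate",
    "transient_truth",
]


@dataclass
class SynthManifest:
    kind: str
    fps: float
    duration_s: float
    seed: int
    noise_sd: float
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SynthManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _contraction_waveform(
    t: np.ndarray, period_s: float, rise_frac: float, hold_frac: float,
    fall_frac: float,
) -> np.ndarray:
    """Smooth periodic contraction/relaxation profile in [0, 1]:
    fast rise, pause at full contraction, slower fall, rest."""
    phase = np.mod(t, period_s) / period_s
    w = np.zeros_like(phase)
    rise = phase < rise_frac
    w[rise] = _smoothstep(phase[rise] / rise_frac)
    hold = (phase >= rise_frac) & (phase < rise_frac + hold_frac)
    w[hold] = 1.0
    falling = (phase >= rise_frac + hold_frac) & (
        phase < rise_frac + hold_frac + fall_frac
    )
    w[falling] = 1.0 - _smoothstep(
        (phase[falling] - rise_frac - hold_frac) / fall_frac
    )
    return w


def make_contraction_video(
    fps: float = 50.0,
    duration_s: float = 4.0,
    period_s: float = 1.0,
    displacement_px: float = 3.0,
    stripe_period_px: float = 16.0,
    contrast: float = 100.0,
    height: int = 64,
    width: int = 64,
    rise_frac: float = 0.2,
    hold_frac: float = 0.04,  # short enough that peak pairing at the
    fall_frac: float = 0.3,   # default 0.1 s gap window still succeeds
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VideoStack, SynthManifest]:
    """Striped texture translating horizontally with a beat-like waveform.

    The stripe is a band-limited sine (period >= 8 px) rendered analytically
    at subpixel displacements d(t) = displacement_px * w(t). Ground-truth
    per-frame-pair speeds |d(t+dt)-d(t)|*fps are stored in the manifest.
    """
    if stripe_period_px < 8:
        raise ValueError("stripe period must be >= 8 px to stay band-limited")
    n = int(round(duration_s * fps))
    if n < 2:
        raise ValueError("duration too short for a video")
    t = np.arange(n) / fps
    d = displacement_px * _contraction_waveform(
        t, period_s, rise_frac, hold_frac, fall_frac
    )
    step = np.abs(np.diff(d))
    if step.size and step.max() > stripe_period_px / 2:
        raise ValueError(
            f"per-frame displacement {step.max():.2f} px exceeds half the "
            f"stripe period ({stripe_period_px / 2:.2f} px); motion would alias"
        )
    x = np.arange(width)
    frames = 127.5 + contrast / 2.0 * np.sin(
        2 * np.pi * (x[None, None, :] - d[:, None, None]) / stripe_period_px
    )
    frames = np.broadcast_to(frames, (n, height, width)).copy()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    frames = np.clip(np.round(frames), 0, 255)

    manifest = SynthManifest(
        kind="contraction",
        fps=fps,
        duration_s=duration_s,
        seed=seed,
        noise_sd=noise_sd,
        params=dict(
            period_s=period_s,
            displacement_px=displacement_px,
            stripe_period_px=stripe_period_px,
            contrast=contrast,
            height=height,
            width=width,
            rise_frac=rise_frac,
            hold_frac=hold_frac,
            fall_frac=fall_frac,
        ),
        truth=dict(
            pair_speeds_px_s=(step * fps).tolist(),
            peak_velocity_px_s=float(step.max() * fps) if step.size else 0.0,
            beat_rate_hz=1.0 / period_s,
            n_beats=int(np.floor(duration_s / period_s + 1e-9)),
        ),
    )
    return VideoStack(frames=frames, fps=fps, channel="gray"), manifest


def _pulse(s: np.ndarray | float, tau_rise: float, tau_decay: float):
    s = np.asarray(s, dtype=np.float64)
    out = np.where(
        s > 0, (1.0 - np.exp(-s / tau_rise)) * np.exp(-s / tau_decay), 0.0
    )
    return out if out.ndim else float(out)


def transient_truth(
    tau_rise: float, tau_decay: float, level_frac: float = 0.10
) -> dict:
    """Timing truths of the double-exponential pulse by root bracketing.

    Crossing times of ``level_frac`` of the pulse peak on the rising and
    falling edges, the analytic peak time, and the derived TTP / T90 /
    width. Independent of the analysis pipeline.
    """
    s_peak = tau_rise * np.log(1.0 + tau_decay / tau_rise)
    g_peak = _pulse(s_peak, tau_rise, tau_decay)
    level = level_frac * g_peak

    def f(s):
        return _pulse(s, tau_rise, tau_decay) - level

    s_rise = brentq(f, 1e-12, s_peak)
    hi = s_peak
    while f(hi) > 0:
        hi += tau_decay
    s_fall = brentq(f, s_peak, hi)
    # max slope of the rising edge (for linearity checks; scales with A)
    ss = np.linspace(0, s_peak, 20001)
    dmax = float(np.max(np.gradient(_pulse(ss, tau_rise, tau_decay), ss)))
    return dict(
        s_peak=float(s_peak),
        g_peak=float(g_peak),
        s_rise10=float(s_rise),
        s_fall10=float(s_fall),
        ttp_s=float(s_peak - s_rise),
        t90_s=float(s_fall - s_peak),
        width10_s=float(s_fall - s_rise),
        max_rise_slope_per_amp=dmax,
    )


def make_calcium_video(
    fps: float = 50.0,
    duration_s: float = 3.0,
    period_s: float | None = 1.5,
    amplitude: float = 300.0,
    tau_rise_s: float = 0.03,
    tau_decay_s: float = 0.17,
    base_level: float = 30.0,
    background_offset: float = 0.0,
    first_transient_s: float = 0.5,
    n_transients: int | None = None,
    height: int = 48,
    width: int = 48,
    sparks: list[dict] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VideoStack, SynthManifest]:
    """Static elliptical cell whose brightness follows a Ca2+ transient
    train, with optional brief bright spark discs.

    Transient onsets sit at ``first_transient_s + k * period_s``; pass
    ``n_transients`` to cap the count (``period_s=None`` with
    ``n_transients=0`` gives a constant dim cell). Pulse amplitude is
    ``amplitude * g`` where g peaks below 1, so brightness may exceed the
    8-bit range only if parameters are pushed; values are clipped.

    Each spark is a dict with keys time_s, y, x, radius, magnitude and
    optional n_frames (default 2).
    """
    n = int(round(duration_s * fps))
    if n < 2:
        raise ValueError("duration too short for a video")
    t = np.arange(n) / fps

    onsets: list[float] = []
    if n_transients != 0:
        k = 0
        while True:
            tk = first_transient_s + k * (period_s or duration_s)
            if tk >= duration_s:
                break
            onsets.append(tk)
            k += 1
            if period_s is None or (
                n_transients is not None and k >= n_transients
            ):
                break
    warnings_list = []
    if len(onsets) >= 2 and period_s is not None and period_s < tau_decay_s:
        warnings_list.append("transients overlap: spacing below tau_decay")

    waveform = np.full(n, base_level, dtype=np.float64)
    for tk in onsets:
        waveform += amplitude * _pulse(t - tk, tau_rise_s, tau_decay_s)

    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    mask = ((yy - cy) / (0.38 * height)) ** 2 + (
        (xx - cx) / (0.42 * width)
    ) ** 2 <= 1.0

    frames = np.zeros((n, height, width), dtype=np.float64)
    frames[:, mask] = waveform[:, None]
    frames += background_offset

    sparks = sparks or []
    for sp in sparks:
        f0 = int(round(sp["time_s"] * fps))
        disc = (yy - sp["y"]) ** 2 + (xx - sp["x"]) ** 2 <= sp["radius"] ** 2
        for df in range(int(sp.get("n_frames", 2))):
            if 0 <= f0 + df < n:
                frames[f0 + df][disc] += sp["magnitude"]

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    frames = np.clip(np.round(frames), 0, 255)

    pulse_truth = transient_truth(tau_rise_s, tau_decay_s)
    manifest = SynthManifest(
        kind="calcium",
        fps=fps,
        duration_s=duration_s,
        seed=seed,
        noise_sd=noise_sd,
        params=dict(
            period_s=period_s,
            amplitude=amplitude,
            tau_rise_s=tau_rise_s,
            tau_decay_s=tau_decay_s,
            base_level=base_level,
            background_offset=background_offset,
            first_transient_s=first_transient_s,
            n_transients=n_transients,
            height=height,
            width=width,
            sparks=sparks,
        ),
        truth=dict(
            onsets_s=onsets,
            n_transients=len(onsets),
            beat_rate_hz=len(onsets) / duration_s,
            t0_s=[tk + pulse_truth["s_rise10"] for tk in onsets],
            ttp_s=pulse_truth["ttp_s"],
            t90_s=pulse_truth["t90_s"],
            width10_s=pulse_truth["width10_s"],
            peak_s=[tk + pulse_truth["s_peak"] for tk in onsets],
            amplitude_scale=amplitude * pulse_truth["g_peak"],
            max_rise_slope=amplitude * pulse_truth["max_rise_slope_per_amp"],
            spark_times_s=[sp["time_s"] for sp in sparks],
        ),
        warnings=warnings_list,
    )
    return VideoStack(frames=frames, fps=fps, channel="green"), manifest


_MAKERS = {
    "contraction": make_contraction_video,
    "calcium": make_calcium_video,
}


def regenerate(manifest: SynthManifest) -> VideoStack:
    """Re-render the video a manifest describes; bit-identical for a fixed
    seed."""
    maker = _MAKERS.get(manifest.kind)
    if maker is None:
        raise ValueError(f"unknown synthetic kind {manifest.kind!r}")
    params = {k: v for k, v in manifest.params.items() if k != "group"}
    stack, _ = maker(
        fps=manifest.fps,
        duration_s=manifest.duration_s,
        noise_sd=manifest.noise_sd,
        seed=manifest.seed,
        **params,
    )
    return stack


def make_group_pair(
    n: int = 6,
    seed: int = 0,
    amplitude_factor: float = 1.0,
    tau_decay_factor: float = 1.0,
    beat_rate_factor: float = 1.0,
    jitter_rel: float = 0.03,
    **base_params,
) -> tuple[list[tuple[VideoStack, SynthManifest]],
           list[tuple[VideoStack, SynthManifest]]]:
    """Matched control and treated calcium recording sets.

    The treated group differs from control only by the three multiplicative
    effect factors (plus per-recording seeds); a small lognormal-like
    amplitude jitter gives each recording biological-looking variability so
    group statistics are well defined. Expected percentage effects are
    recorded in every treated manifest.
    """
    if n < 2:
        raise ValueError("need n >= 2 recordings per group (SEM undefined)")
    base = dict(
        fps=50.0, duration_s=3.0, period_s=1.5, amplitude=300.0,
        tau_rise_s=0.03, tau_decay_s=0.17, base_level=30.0,
        first_transient_s=0.5, height=48, width=48, noise_sd=0.0,
    )
    base.update(base_params)

    rng = np.random.default_rng(seed)
    control_truth = transient_truth(base["tau_rise_s"], base["tau_decay_s"])
    treated_truth = transient_truth(
        base["tau_rise_s"], base["tau_decay_s"] * tau_decay_factor
    )
    expected_pct = dict(
        dfdt_max=100.0 * amplitude_factor,
        t90_s=100.0 * treated_truth["t90_s"] / control_truth["t90_s"],
        beat_rate_hz=100.0 * beat_rate_factor,
    )

    def build(group_seed_offset, amp_f, tau_f, rate_f, label):
        out = []
        for i in range(n):
            jitter = 1.0 + np.clip(rng.normal(0.0, jitter_rel), -0.3, 0.3)
            params = dict(base)
            params["amplitude"] = base["amplitude"] * amp_f * jitter
            params["tau_decay_s"] = base["tau_decay_s"] * tau_f
            if base["period_s"] is not None:
                params["period_s"] = base["period_s"] / rate_f
            stack, manifest = make_calcium_video(
                seed=seed * 100000 + group_seed_offset + i, **params
            )
            manifest.params["group"] = label
            manifest.truth["expected_pct"] = (
                expected_pct if label == "treated" else
                {k: 100.0 for k in expected_pct}
            )
            out.append((stack, manifest))
        return out

    controls = build(0, 1.0, 1.0, 1.0, "control")
    treated = build(50000, amplitude_factor, tau_decay_factor,
                    beat_rate_factor, "treated")
    return controls, treated
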