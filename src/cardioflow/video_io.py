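"""Loading and saving of video stacks and 1-D traces.

Videos are held as float arrays on the 8-bit intensity scale [0, 255]
regardless of on-disk bit depth; 16-bit input is rescaled linearly by the
data-type maximum (not the per-video maximum) so absolute intensities stay
comparable across recordings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from cardioflow import _avi

__all__ = [
    "VideoStack",
    "TimeSeries",
    "load_video",
    "save_video",
    "load_trace",
    "save_trace",
    "VideoFormatError",
    "InsufficientFramesError",
    "MissingMetadataError",
    "TraceParseError",
]


class VideoFormatError(ValueError):
    """File is not a readable video in a supported container."""


class InsufficientFramesError(VideoFormatError):
    """Video has fewer than two frames."""


class MissingMetadataError(ValueError):
    """Frame rate is not recorded in the container and no override given."""


class TraceParseError(ValueError):
    """CSV trace could not be parsed."""


@dataclass
class VideoStack:
    """An ordered stack of single-channel frames with a frame rate.

    ``frames`` has shape (n_frames, height, width), dtype float, values in
    [0, 255].
    """

    frames: np.ndarray
    fps: float
    channel: str = "gray"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (n, h, w), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InsufficientFramesError(
                f"need at least 2 frames, got {self.frames.shape[0]}"
            )
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        lo, hi = self.frames.min(), self.frames.max()
        if lo < 0 or hi > 255:
            raise ValueError(f"pixel values outside [0, 255]: [{lo}, {hi}]")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class TimeSeries:
    """Uniformly sampled scalar series (velocity or intensity trace)."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def duration_s(self) -> float:
        return self.values.size * self.dt


def _extract_channel(raw: np.ndarray, channel: str) -> tuple[np.ndarray, str]:
    if raw.ndim == 4 and raw.shape[-1] in (3, 4):
        rgb = raw[..., :3].astype(np.float64)
        if channel == "green":
            return rgb[..., 1], "green"
        if channel == "gray":
            # ITU-R BT.601 luma
            return rgb @ np.array([0.299, 0.587, 0.114]), "gray"
        raise ValueError(f"unknown channel selector {channel!r}")
    if raw.ndim == 3:
        return raw.astype(np.float64), "gray"
    raise VideoFormatError(f"unsupported video array shape {raw.shape}")


def _rescale_to_8bit(frames: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if dtype == np.uint8:
        return frames
    if dtype == np.uint16:
        return frames * (255.0 / 65535.0)
    if np.issubdtype(dtype, np.integer):
        return frames * (255.0 / np.iinfo(dtype).max)
    raise VideoFormatError(f"unsupported pixel dtype {dtype}")


def _tiff_fps(tif: tifffile.TiffFile) -> float | None:
    meta = tif.imagej_metadata
    if meta:
        if meta.get("fps"):
            return float(meta["fps"])
        if meta.get("finterval"):
            return 1.0 / float(meta["finterval"])
    return None


def load_video(
    path, channel: str = "green", fps_override: float | None = None
) -> VideoStack:
    """Load an AVI or multi-page TIFF into a :class:`VideoStack`.

    For RGB input the requested color plane is extracted (``green`` takes
    the green plane, ``gray`` a luma combination); grayscale input is used
    as-is. 16-bit data is rescaled linearly to the [0, 255] scale.

    Raises :class:`MissingMetadataError` when the container records no frame
    rate and ``fps_override`` is not given — every kinetic parameter is in
    seconds, so a silently assumed rate would corrupt downstream numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    fps_meta: float | None = None
    is_color = None
    if suffix in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tif:
                series = tif.series[0]
                raw = series.asarray()
                is_color = series.axes.endswith("S")
                fps_meta = _tiff_fps(tif)
        except (tifffile.TiffFileError, ValueError, IndexError) as exc:
            raise VideoFormatError(f"unreadable TIFF {path}: {exc}") from exc
    elif suffix == ".avi":
        try:
            raw, avi_fps = _avi.read_avi(path)
        except _avi.AviError as exc:
            raise VideoFormatError(f"unreadable AVI {path}: {exc}") from exc
        fps_meta = avi_fps if avi_fps > 0 else None
    else:
        raise VideoFormatError(f"unsupported container {suffix!r} for {path}")

    raw = np.asarray(raw)
    if is_color is None:  # AVI reader output is unambiguous
        is_color = raw.ndim == 4
    if raw.ndim == 2 or (raw.ndim == 3 and is_color):
        raise InsufficientFramesError(f"{path} holds a single frame")
    if raw.shape[0] < 2:
        raise InsufficientFramesError(f"{path} has fewer than 2 frames")

    dtype = raw.dtype
    frames, used_channel = _extract_channel(raw, channel)
    frames = _rescale_to_8bit(frames, dtype)

    fps = fps_override if fps_override is not None else fps_meta
    if fps is None:
        raise MissingMetadataError(
            f"{path} records no frame rate; pass fps_override explicitly"
        )
    return VideoStack(frames=frames, fps=float(fps), channel=used_channel)


def save_video(stack: VideoStack, path) -> None:
    """Write a stack as an 8-bit grayscale TIFF (with fps metadata) or AVI.

    Values are rounded to the uint8 grid; the round trip is bit-exact for
    stacks whose values already sit on that grid.
    """
    path = Path(path)
    data = np.clip(np.round(stack.frames), 0, 255).astype(np.uint8)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path, data, imagej=True, metadata={"fps": float(stack.fps)}
        )
    elif suffix == ".avi":
        _avi.write_avi(path, data, stack.fps)
    else:
        raise VideoFormatError(f"unsupported output container {suffix!r}")


def load_trace(path, dt: float) -> TimeSeries:
    """Read a single-column CSV (optional header) into a :class:`TimeSeries`."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    path = Path(path)
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    rows = [(i, ln) for i, ln in enumerate(lines) if ln]
    if not rows:
        raise TraceParseError(f"{path} contains no data rows")
    start = 0
    try:  # tolerate a single header row
        float(rows[0][1].split(",")[0])
    except ValueError:
        start = 1
        if len(rows) == 1:
            raise TraceParseError(f"{path} contains only a header row")
    for i, ln in rows[start:]:
        cell = ln.split(",")[0]
        try:
            values.append(float(cell))
        except ValueError as exc:
            raise TraceParseError(
                f"{path} row {i + 1}: non-numeric value {cell!r}"
            ) from exc
    return TimeSeries(values=np.array(values), dt=dt)


def save_trace(series: TimeSeries, path, value_name: str = "value") -> None:
    """Write a series as a two-column CSV (time_s, <value_name>)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"time_s,{value_name}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.6f},{v:.6f}\n")
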