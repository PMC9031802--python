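"""Minimal uncompressed AVI (RIFF) reader/writer.

Supports only BI_RGB device-independent bitmaps: 8-bit palettized grayscale
and 24-bit BGR, which is what this package writes. Compressed streams cannot
be decoded here (no codec stack is assumed to exist) and raise a format
error on read.
"""

from __future__ import annotations

import struct
import warnings

import numpy as np

__all__ = ["read_avi", "write_avi", "AviError"]


class AviError(ValueError):
    """Malformed or unsupported AVI content."""


def _pad4(n: int) -> int:
    return (n + 3) & ~3


def _row_stride(width: int, bitcount: int) -> int:
    return _pad4(width * bitcount // 8)


def write_avi(path, frames: np.ndarray, fps: float) -> None:
    """Write an uncompressed AVI.

    ``frames`` is uint8 with shape (n, h, w) for grayscale (written as an
    8-bit palettized DIB with an identity gray palette) or (n, h, w, 3) RGB
    (written as 24-bit BGR).
    """
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        raise AviError("AVI writer requires uint8 frames")
    if frames.ndim == 3:
        n, h, w = frames.shape
        bitcount = 8
    elif frames.ndim == 4 and frames.shape[-1] == 3:
        n, h, w = frames.shape[:3]
        bitcount = 24
    else:
        raise AviError(f"unsupported frame array shape {frames.shape}")
    if n < 1:
        raise AviError("no frames to write")
    if fps <= 0:
        raise AviError("fps must be positive")

    stride = _row_stride(w, bitcount)
    frame_bytes = stride * h

    def dib(frame: np.ndarray) -> bytes:
        # bottom-up rows, each padded to a 4-byte boundary; 24-bit is BGR
        if bitcount == 8:
            rows = frame[::-1]
        else:
            rows = frame[::-1, :, ::-1].reshape(h, w * 3)
        padded = np.zeros((h, stride), dtype=np.uint8)
        padded[:, : rows.shape[1]] = rows.reshape(h, -1)
        return padded.tobytes()

    # rate/scale pair encodes fps exactly enough for our purposes
    scale = 1_000_000
    rate = int(round(fps * scale))

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # dwMicroSecPerFrame
        int(frame_bytes * fps) + 1,  # dwMaxBytesPerSec
        0,  # dwPaddingGranularity
        0x10,  # dwFlags = AVIF_HASINDEX
        n,  # dwTotalFrames
        0,  # dwInitialFrames
        1,  # dwStreams
        frame_bytes,  # dwSuggestedBufferSize
        w,
        h,
        0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIi4H",
        b"vids",      # fccType
        b"DIB ",      # fccHandler
        0, 0, 0, 0,   # flags, priority, language, initial frames
        scale,
        rate,
        0,            # dwStart
        n,            # dwLength
        frame_bytes,  # dwSuggestedBufferSize
        0,            # dwQuality
        0,            # dwSampleSize
        0, 0, w, h,   # rcFrame
    )
    bmih = struct.pack(
        "<IiiHHIIiiII",
        40, w, h, 1, bitcount, 0, frame_bytes, 0, 0,
        256 if bitcount == 8 else 0, 0,
    )
    if bitcount == 8:
        palette = bytes(
            b for i in range(256) for b in (i, i, i, 0)
        )
        strf = bmih + palette
    else:
        strf = bmih

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        data = struct.pack("<4sI", fourcc, len(payload)) + payload
        if len(payload) % 2:
            data += b"\x00"
        return data

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    strl = lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b""
    offsets = []
    for i in range(n):
        offsets.append(len(movi_payload) + 4)  # offset from 'movi' fourcc
        movi_payload += chunk(b"00db", dib(frames[i]))
    movi = lst(b"movi", movi_payload)

    idx_entries = b"".join(
        struct.pack("<4sIII", b"00db", 0x10, off, frame_bytes)
        for off in offsets
    )
    idx1 = chunk(b"idx1", idx_entries)

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(struct.pack("<4sI", b"RIFF", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc, size = struct.unpack_from("<4sI", buf, pos)
        body = pos + 8
        yield fourcc, body, body + size
        pos = body + size + (size % 2)


def read_avi(path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI written by :func:`write_avi` (or compatible).

    Returns ``(frames, fps)`` where frames is uint8 (n, h, w) or (n, h, w, 3)
    RGB.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise AviError("not a RIFF/AVI file")

    strh = strf = None
    frame_chunks: list[tuple[int, int]] = []

    def walk(start: int, end: int) -> None:
        nonlocal strh, strf
        for fourcc, body, bend in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(body + 4, bend)
            elif fourcc == b"strh" and strh is None:
                strh = buf[body:bend]
            elif fourcc == b"strf" and strf is None:
                strf = buf[body:bend]
            elif fourcc in (b"00db", b"00dc"):
                frame_chunks.append((body, bend))

    walk(12, len(buf))

    if strf is None or len(strf) < 40:
        raise AviError("missing stream format header")
    (_, w, h, _, bitcount, compression) = struct.unpack_from("<IiiHHI", strf, 0)
    if compression != 0:
        raise AviError(
            f"compressed AVI stream (biCompression={compression:#x}) is not "
            "decodable without a codec; re-export as uncompressed AVI or TIFF"
        )
    if bitcount not in (8, 24):
        raise AviError(f"unsupported bit depth {bitcount}")
    if h <= 0 or w <= 0:
        raise AviError("invalid frame dimensions")
    if not frame_chunks:
        raise AviError("no frame data chunks found")

    fps = 0.0
    if strh is not None and len(strh) >= 32:
        scale, rate = struct.unpack_from("<II", strh, 20)
        if scale > 0 and rate > 0:
            fps = rate / scale
    if fps <= 0:
        warnings.warn("AVI stream header lacks a usable rate; fps unknown")

    stride = _row_stride(w, bitcount)
    frames = []
    for body, bend in frame_chunks:
        raw = np.frombuffer(buf[body:bend], dtype=np.uint8)
        if raw.size < stride * h:
            raise AviError("truncated frame chunk")
        rows = raw[: stride * h].reshape(h, stride)
        if bitcount == 8:
            frames.append(rows[::-1, :w])
        else:
            bgr = rows[:, : w * 3].reshape(h, w, 3)
            frames.append(bgr[::-1, :, ::-1])
    return np.stack(frames), fps
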