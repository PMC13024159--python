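"""Minimal European Data Format (EDF) reader/writer for interoperability.

Implements the plain EDF variant: ASCII header (256 bytes + 256 per signal)
followed by little-endian int16 samples, record-major then signal-major.
Values round-trip up to the 16-bit quantization implied by the physical
calibration range.  No annotations, no EDF+ extensions.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .preprocessing import RawRecording

__all__ = ["read_edf", "write_edf"]


class EDFFormatError(ValueError):
    pass


def _field(text: str, width: int) -> bytes:
    s = text[:width].ljust(width)
    return s.encode("ascii")


def write_edf(rec: RawRecording, path) -> None:
    """Write a recording as single-data-record EDF (int16 quantized)."""
    c, t = rec.signals.shape
    duration = t / rec.sfreq
    phys_min = rec.signals.min(axis=1)
    phys_max = rec.signals.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((rec.signals - phys_min[:, None]) / scale[:, None]
                       + dig_min).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + c)), 8),
        _field("", 44),
        _field("1", 8),
        _field(f"{duration:.6g}", 8),
        _field(str(c), 4),
    ])
    per = [
        b"".join(_field(n, 16) for n in rec.channel_names),
        b"".join(_field("", 80) for _ in range(c)),
        b"".join(_field("uV", 8) for _ in range(c)),
        b"".join(_field(f"{v:.6g}", 8) for v in phys_min),
        b"".join(_field(f"{v:.6g}", 8) for v in phys_max),
        b"".join(_field(str(dig_min), 8) for _ in range(c)),
        b"".join(_field(str(dig_max), 8) for _ in range(c)),
        b"".join(_field("", 80) for _ in range(c)),
        b"".join(_field(str(t), 8) for _ in range(c)),
        b"".join(_field("", 32) for _ in range(c)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in per:
            fh.write(block)
        fh.write(digital.tobytes())


def _ascii(buf: bytes) -> str:
    return buf.decode("ascii", errors="replace").strip()


def read_edf(path) -> RawRecording:
    data = Path(path).read_bytes()
    if len(data) < 256:
        raise EDFFormatError("file shorter than an EDF header")
    try:
        n_records = int(_ascii(data[236:244]))
        duration = float(_ascii(data[244:252]))
        c = int(_ascii(data[252:256]))
    except ValueError as e:
        raise EDFFormatError(f"malformed EDF header: {e}") from e
    if c < 1:
        raise EDFFormatError("EDF header declares no signals")
    need = 256 + 256 * c
    if len(data) < need:
        raise EDFFormatError("truncated EDF signal header")
    off = 256

    def block(width: int) -> list[str]:
        nonlocal off
        out = [_ascii(data[off + i * width: off + (i + 1) * width])
               for i in range(c)]
        off += width * c
        return out

    labels = block(16)
    block(80)  # transducer
    block(8)   # physical dimension
    phys_min = np.array([float(v) for v in block(8)])
    phys_max = np.array([float(v) for v in block(8)])
    dig_min = np.array([int(v) for v in block(8)])
    dig_max = np.array([int(v) for v in block(8)])
    block(80)  # prefiltering
    spr = np.array([int(v) for v in block(8)])
    block(32)  # reserved
    if len(set(spr.tolist())) != 1:
        raise EDFFormatError("mixed sampling rates are not supported")
    t_rec = int(spr[0])
    expect = need + 2 * n_records * t_rec * c
    if len(data) < expect:
        raise EDFFormatError("EDF data section truncated")
    raw = np.frombuffer(data[need:expect], dtype="<i2")
    raw = raw.reshape(n_records, c, t_rec)
    digital = np.concatenate([raw[r] for r in range(n_records)], axis=1)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    signals = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    sfreq = t_rec / duration
    return RawRecording(signals=signals, sfreq=sfreq, channel_names=labels)
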