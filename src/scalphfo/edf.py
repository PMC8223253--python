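"""Minimal EDF (European Data Format) codec.

Implements the classic 16-bit EDF layout: a 256-byte fixed header, 256 bytes
per signal, then contiguous data records of little-endian int16 samples.
Only equal-rate signals are supported; annotations travel in a plain-text
sidecar (see :mod:`scalphfo.eeg_io`), not as EDF+ TAL streams.

Reference: Kemp et al., the EDF field layout as published at edfplus.info.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

__all__ = ["EDFFormatError", "read_edf_raw", "write_edf_raw"]

_DIGITAL_MIN = -32768
_DIGITAL_MAX = 32767


class EDFFormatError(ValueError):
    """Malformed or unsupported EDF content."""


@dataclass
class _RawEDF:
    labels: list[str]
    fs: float
    data: np.ndarray  # (n_channels, n_samples) float64, physical units
    physical_dim: str


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise EDFFormatError(f"header field {text!r} exceeds {width} ascii bytes")
    return raw.ljust(width)


def _fmt_float(value: float, width: int) -> bytes:
    for digits in range(width - 2, -1, -1):
        text = f"{value:.{digits}f}"
        if len(text) <= width:
            return _field(text, width)
    raise EDFFormatError(f"cannot format {value} in {width} bytes")


def write_edf_raw(
    path: str | os.PathLike,
    labels: list[str],
    fs: float,
    data: np.ndarray,
    physical_dim: str = "uV",
    patient_id: str = "X X X X",
    recording_id: str = "Startdate X X X X",
) -> None:
    """Write physical-unit signals as 16-bit EDF.

    Each channel gets its own physical range spanning its data (symmetric,
    never degenerate), so quantization error is at most one step of
    (phys_max - phys_min) / 2**16.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] == 0 or data.shape[1] == 0:
        raise EDFFormatError("need a non-empty 2-D channel x sample array")
    if len(labels) != data.shape[0]:
        raise EDFFormatError("label count does not match channel count")
    if len(set(labels)) != len(labels):
        raise EDFFormatError("duplicate channel labels")
    if fs <= 0:
        raise EDFFormatError("sampling rate must be positive")
    if not np.isfinite(data).all():
        raise EDFFormatError("non-finite samples cannot be written")

    n_ch, n_samp = data.shape
    # One-second records when the length divides evenly, else one big record.
    if abs(fs - round(fs)) < 1e-9 and n_samp % round(fs) == 0:
        spr = int(round(fs))  # samples per record per signal
        n_records = n_samp // spr
        record_dur = 1.0
    else:
        spr = n_samp
        n_records = 1
        record_dur = n_samp / fs

    phys_min = np.empty(n_ch)
    phys_max = np.empty(n_ch)
    for i in range(n_ch):
        span = float(np.max(np.abs(data[i])))
        span = max(span, 1e-6)  # keep the range non-degenerate for flat channels
        phys_max[i] = span
        phys_min[i] = -span

    header = bytearray()
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field(recording_id, 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field(str(n_records), 8)
    header += _fmt_float(record_dur, 8)
    header += _field(str(n_ch), 4)

    for lab in labels:
        header += _field(lab, 16)
    header += b" " * (80 * n_ch)  # transducer type
    for _ in range(n_ch):
        header += _field(physical_dim, 8)
    for i in range(n_ch):
        header += _fmt_float(phys_min[i], 8)
    for i in range(n_ch):
        header += _fmt_float(phys_max[i], 8)
    for _ in range(n_ch):
        header += _field(str(_DIGITAL_MIN), 8)
    for _ in range(n_ch):
        header += _field(str(_DIGITAL_MAX), 8)
    header += b" " * (80 * n_ch)  # prefiltering
    for _ in range(n_ch):
        header += _field(str(spr), 8)
    header += b" " * (32 * n_ch)

    # Quantize against the ranges as re-parsed from their ascii header fields,
    # so read(write(x)) error stays within one quantization step.
    pmin = np.array([float(bytes(header[256 + n_ch * 104 + 8 * i: 256 + n_ch * 104 + 8 * (i + 1)])) for i in range(n_ch)])
    pmax = np.array([float(bytes(header[256 + n_ch * 112 + 8 * i: 256 + n_ch * 112 + 8 * (i + 1)])) for i in range(n_ch)])
    gain = (pmax - pmin) / (_DIGITAL_MAX - _DIGITAL_MIN)
    digital = np.rint((data - pmin[:, None]) / gain[:, None] + _DIGITAL_MIN)
    digital = np.clip(digital, _DIGITAL_MIN, _DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # Record-major, signal-major within record.
        blocks = digital.reshape(n_ch, n_records, spr)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())


def read_edf_raw(path: str | os.PathLike) -> _RawEDF:
    """Read a 16-bit EDF file into physical units.

    Raises :class:`EDFFormatError` on malformed headers, duplicate labels,
    or signals with differing sampling rates.
    """
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise EDFFormatError("truncated EDF header")
        try:
            n_records = int(fixed[236:244].decode("ascii").strip())
            record_dur = float(fixed[244:252].decode("ascii").strip())
            n_ch = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise EDFFormatError(f"unparseable EDF header: {exc}") from exc
        if n_ch <= 0 or n_records <= 0 or record_dur <= 0:
            raise EDFFormatError("EDF header reports a degenerate record layout")

        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise EDFFormatError("truncated EDF signal headers")

        def col(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                sig[base + width * i: base + width * (i + 1)].decode("ascii", "replace").strip()
                for i in range(n_ch)
            ]

        labels = col(0, 16)
        if len(set(labels)) != len(labels):
            raise EDFFormatError(f"duplicate channel labels in {labels}")
        dims = col(96, 8)
        try:
            pmin = np.array([float(x) for x in col(104, 8)])
            pmax = np.array([float(x) for x in col(112, 8)])
            dmin = np.array([int(x) for x in col(120, 8)])
            dmax = np.array([int(x) for x in col(128, 8)])
            spr = np.array([int(x) for x in col(216, 8)])
        except ValueError as exc:
            raise EDFFormatError(f"unparseable signal header: {exc}") from exc
        if np.any(dmax <= dmin) or np.any(pmax <= pmin):
            raise EDFFormatError("non-increasing digital or physical ranges")
        if len(set(spr.tolist())) != 1:
            raise EDFFormatError("multi-rate EDF files are not supported")
        spr0 = int(spr[0])
        fs = spr0 / record_dur
        if abs(fs - round(fs)) < 1e-6:
            fs = float(round(fs))

        payload = fh.read(2 * spr0 * n_ch * n_records)
        expected = 2 * spr0 * n_ch * n_records
        if len(payload) < expected:
            raise EDFFormatError("EDF data payload shorter than header promises")

    digital = np.frombuffer(payload, dtype="<i2").reshape(n_records, n_ch, spr0)
    digital = digital.transpose(1, 0, 2).reshape(n_ch, n_records * spr0).astype(np.float64)
    gain = (pmax - pmin) / (dmax - dmin)
    physical = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    dim = dims[0] if dims else "uV"
    if math.isnan(fs):
        raise EDFFormatError("invalid sampling rate")
    return _RawEDF(labels=labels, fs=fs, data=physical, physical_dim=dim)
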