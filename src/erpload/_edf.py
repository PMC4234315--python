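"""Minimal EDF (European Data Format) reader/writer.

Implements the 16-bit integer EDF layout: a 256-byte fixed header, 256 bytes
per signal, then little-endian int16 data records.  Only the subset needed to
round-trip continuous recordings written by this package is supported:

* every signal shares one sampling rate (integer Hz);
* the recording is stored as 1-second data records, the last record padded
  with zeros; the true sample count is stashed in the 44-byte reserved header
  field as ``NSAMP=<n>`` so our reader can drop the padding.

Physical min/max are integer microvolt bounds so the 8-character ASCII header
fields represent them exactly and the digital<->physical mapping incurs only
16-bit quantization error.
"""

from __future__ import annotations

import math
import os
from datetime import datetime

import numpy as np

from .errors import ConfigError, DataValidationError

_DIG_MIN = -32768
_DIG_MAX = 32767


def _fixed(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ConfigError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def quantization_step(data: np.ndarray) -> float:
    """Physical size of one digital unit for the bounds chosen by write_edf."""
    pmin, pmax = _phys_bounds(data)
    return (pmax - pmin) / (_DIG_MAX - _DIG_MIN)


def _phys_bounds(channel: np.ndarray) -> tuple[int, int]:
    lo = math.floor(float(np.min(channel)))
    hi = math.ceil(float(np.max(channel)))
    if hi <= lo:
        hi = lo + 1
    return lo, hi


def write_edf(
    path: str | os.PathLike,
    data: np.ndarray,
    channel_labels: list[str],
    sfreq: float,
    start_time: float = 0.0,
) -> None:
    """Write ``data`` (channels x samples, microvolts) as a 16-bit EDF file."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(channel_labels):
        raise ConfigError("data must be channels x samples matching labels")
    if len(channel_labels) == 0:
        raise ConfigError("EDF requires at least one channel")
    if sfreq <= 0 or abs(sfreq - round(sfreq)) > 1e-9:
        raise ConfigError(f"EDF writer requires an integer sampling rate, got {sfreq}")
    sfreq_i = int(round(sfreq))
    n_ch, n_samples = data.shape
    n_records = max(1, math.ceil(n_samples / sfreq_i))

    bounds = [_phys_bounds(data[c]) for c in range(n_ch)]
    header_bytes = 256 + 256 * n_ch

    dt = datetime(2000, 1, 1)
    parts = [
        _fixed("0", 8),
        _fixed("X", 80),
        _fixed("X", 80),
        _fixed(dt.strftime("%d.%m.%y"), 8),
        _fixed(dt.strftime("%H.%M.%S"), 8),
        _fixed(str(header_bytes), 8),
        _fixed(f"NSAMP={n_samples} T0={start_time:g}", 44),
        _fixed(str(n_records), 8),
        _fixed("1", 8),
        _fixed(str(n_ch), 4),
    ]
    for label in channel_labels:
        parts.append(_fixed(label, 16))
    parts += [_fixed("", 80)] * n_ch
    parts += [_fixed("uV", 8)] * n_ch
    for lo, _ in bounds:
        parts.append(_fixed(str(lo), 8))
    for _, hi in bounds:
        parts.append(_fixed(str(hi), 8))
    parts += [_fixed(str(_DIG_MIN), 8)] * n_ch
    parts += [_fixed(str(_DIG_MAX), 8)] * n_ch
    parts += [_fixed("BP 1-15Hz offline", 80)] * n_ch
    parts += [_fixed(str(sfreq_i), 8)] * n_ch
    parts += [_fixed("", 32)] * n_ch
    header = b"".join(parts)
    assert len(header) == header_bytes

    padded = np.zeros((n_ch, n_records * sfreq_i), dtype=np.int16)
    for c in range(n_ch):
        lo, hi = bounds[c]
        scale = (hi - lo) / (_DIG_MAX - _DIG_MIN)
        dig = np.round((data[c] - lo) / scale) + _DIG_MIN
        padded[c, :n_samples] = np.clip(dig, _DIG_MIN, _DIG_MAX).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header)
        # records interleave channels: all samples of ch0 for record r, then ch1, ...
        view = padded.reshape(n_ch, n_records, sfreq_i)
        for r in range(n_records):
            fh.write(view[:, r, :].tobytes())


def read_edf(path: str | os.PathLike) -> tuple[np.ndarray, list[str], float, float]:
    """Read an EDF file written by :func:`write_edf`.

    Returns ``(data, channel_labels, sfreq, start_time)``.
    """
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise DataValidationError(f"{path}: truncated EDF header")
        try:
            header_bytes = int(head[184:192])
            reserved = head[192:236].decode("ascii").strip()
            n_records = int(head[236:244])
            record_duration = float(head[244:252])
            n_ch = int(head[252:256])
        except ValueError as exc:
            raise DataValidationError(f"{path}: corrupt EDF header ({exc})") from exc
        sig_head = fh.read(256 * n_ch)
        if len(sig_head) < 256 * n_ch:
            raise DataValidationError(f"{path}: truncated EDF signal headers")

        def field(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = field(0, 16)
        if len(set(labels)) != n_ch:
            raise DataValidationError(f"{path}: duplicate channel labels {labels}")
        phys_min = [float(v) for v in field(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in field(16 + 80 + 8 + 8, 8)]
        dig_min = [int(v) for v in field(16 + 80 + 8 + 16, 8)]
        dig_max = [int(v) for v in field(16 + 80 + 8 + 24, 8)]
        spr = [int(v) for v in field(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise DataValidationError(f"{path}: heterogeneous sampling rates unsupported")
        samples_per_record = spr[0]
        sfreq = samples_per_record / record_duration

        expected = header_bytes + 2 * n_records * n_ch * samples_per_record
        if size != expected:
            raise DataValidationError(
                f"{path}: file size {size} != expected {expected} (truncated or corrupt)"
            )
        raw = np.frombuffer(fh.read(), dtype="<i2")

    raw = raw.reshape(n_records, n_ch, samples_per_record)
    dig = np.ascontiguousarray(raw.transpose(1, 0, 2)).reshape(n_ch, -1).astype(float)
    data = np.empty_like(dig)
    for c in range(n_ch):
        scale = (phys_max[c] - phys_min[c]) / (dig_max[c] - dig_min[c])
        data[c] = (dig[c] - dig_min[c]) * scale + phys_min[c]

    n_samples = n_records * samples_per_record
    start_time = 0.0
    for token in reserved.split():
        if token.startswith("NSAMP="):
            n_samples = int(token[6:])
        elif token.startswith("T0="):
            start_time = float(token[3:])
    return data[:, :n_samples], labels, sfreq, start_time
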