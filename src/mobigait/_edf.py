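"""Minimal EDF writer and header inspection.

Only writing is implemented here; reading goes through :mod:`mne`.  The EDF
container is a fixed-offset ASCII header followed by little-endian int16 data
records, with per-channel physical/digital scaling.  One data record per
second is used, so the sampling rate must be a positive integer.
"""

from __future__ import annotations

import numpy as np


class EdfFormatError(ValueError):
    """Raised when an EDF header field cannot be honoured or parsed."""


def _ascii(field: str, width: int) -> bytes:
    out = field.encode("ascii", errors="replace")
    if len(out) > width:
        out = out[:width]
    return out.ljust(width)


def _num8(value: float) -> str:
    """Format a number into at most 8 ASCII characters, losing precision
    rather than truncating digits mid-field."""
    for prec in range(6, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{value:.0e}"[:8]


def peek_labels(path) -> list[str]:
    """Read the channel labels straight from the fixed-offset EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EdfFormatError(f"{path}: truncated EDF header (< 256 bytes)")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as err:
            raise EdfFormatError(
                f"{path}: invalid 'number of signals' header field"
            ) from err
        raw = fh.read(16 * ns)
    if len(raw) < 16 * ns:
        raise EdfFormatError(f"{path}: truncated signal-label header block")
    return [raw[i * 16:(i + 1) * 16].decode("ascii").strip() for i in range(ns)]


def write_edf(path, data: np.ndarray, fs: float, labels: list[str],
              physical_dim: str = "uV") -> None:
    """Write ``data`` (channels x samples) as EDF with 1-s data records."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise EdfFormatError("data must be a channels x samples matrix")
    n_ch, n_samp = data.shape
    if len(labels) != n_ch:
        raise EdfFormatError("label count does not match channel count")
    if len(set(labels)) != n_ch:
        raise EdfFormatError("duplicate channel labels")
    fs_int = int(round(fs))
    if fs_int <= 0 or abs(fs - fs_int) > 1e-9:
        raise EdfFormatError(f"EDF writer requires an integer sampling rate, got {fs}")

    # pad to a whole number of 1-s records
    n_rec = int(np.ceil(n_samp / fs_int))
    padded = np.zeros((n_ch, n_rec * fs_int))
    padded[:, :n_samp] = data

    # per-channel physical range, symmetric so zero maps to digital zero;
    # quantize the range to what the 8-char ASCII field can carry so the
    # reader's scaling matches the writer's exactly
    absmax = np.maximum(np.abs(padded).max(axis=1), 1e-9)
    absmax = np.array([float(_num8(v)) for v in absmax])
    dig_max = 32767
    scale = absmax / dig_max
    digital = np.round(padded / scale[:, None]).astype("<i2")

    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),              # patient id
        _ascii("Startdate X X X X", 80),    # recording id
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(str(256 + 256 * n_ch), 8),
        _ascii("", 44),
        _ascii(str(n_rec), 8),
        _ascii("1", 8),                     # record duration, seconds
        _ascii(str(n_ch), 4),
    ])
    sig = b"".join(_ascii(lab, 16) for lab in labels)
    sig += b"".join(_ascii("", 80) for _ in range(n_ch))
    sig += b"".join(_ascii(physical_dim, 8) for _ in range(n_ch))
    sig += b"".join(_ascii(_num8(-absmax[i]), 8) for i in range(n_ch))
    sig += b"".join(_ascii(_num8(absmax[i]), 8) for i in range(n_ch))
    sig += b"".join(_ascii(str(-dig_max), 8) for _ in range(n_ch))
    sig += b"".join(_ascii(str(dig_max), 8) for _ in range(n_ch))
    sig += b"".join(_ascii("", 80) for _ in range(n_ch))
    sig += b"".join(_ascii(str(fs_int), 8) for _ in range(n_ch))
    sig += b"".join(_ascii("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        # records: for each second, every channel's block of fs samples
        rec = digital.reshape(n_ch, n_rec, fs_int).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec).tobytes())
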