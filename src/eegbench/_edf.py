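"""Minimal EDF / BDF codec.

Implements just enough of the European Data Format (16-bit) and its BioSemi
24-bit variant to round-trip continuous multichannel data in μV: fixed
256-byte header, 256 bytes per signal, little-endian integer data records.
Annotations channels and discontinuous files are not supported.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

_EDF_DIG = 32767
_BDF_DIG = 8388607  # 2**23 - 1


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ascii bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    """Render a number into a fixed ascii field without silent truncation."""
    if float(value) == int(value) and abs(value) < 10 ** width:
        return _ascii(int(value), width)
    for prec in range(width, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot encode {value} in {width} bytes")


def _phys_limit(data: np.ndarray) -> int:
    """Symmetric integer physical range that covers the data exactly
    representable in the 8-char header field (so the decoder gain is exact)."""
    peak = float(np.max(np.abs(data))) if data.size else 1.0
    return max(1, int(math.ceil(peak)))


def write(path: str | Path, data: np.ndarray, rate: float,
          labels: list[str], kind: str = "bdf",
          meta: dict | None = None) -> None:
    """Write channels x samples μV data as one continuous EDF/BDF file."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if n_ch == 0 or n_samp == 0:
        raise ValueError("cannot write an empty recording")
    kind = kind.lower()
    if kind not in ("edf", "bdf"):
        raise ValueError(f"unknown format {kind!r}")
    dig = _BDF_DIG if kind == "bdf" else _EDF_DIG

    # One-second records when the sample count allows, else a single record.
    if rate == int(rate) and n_samp % int(rate) == 0:
        spr, n_rec, rec_dur = int(rate), n_samp // int(rate), 1.0
    else:
        spr, n_rec, rec_dur = n_samp, 1, n_samp / rate

    meta = meta or {}
    header = bytearray()
    if kind == "bdf":
        header += b"\xffBIOSEMI "[:8]
    else:
        header += _ascii("0", 8)
    header += _ascii(meta.get("subject", "X"), 80)
    header += _ascii(meta.get("recording", "eegbench"), 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + n_ch), 8)
    header += _ascii("24BIT" if kind == "bdf" else "", 44)
    header += _ascii(n_rec, 8)
    header += _num(rec_dur, 8)
    header += _ascii(n_ch, 4)

    pmaxs = [_phys_limit(data[c]) for c in range(n_ch)]
    for field, width in (
        (labels, 16),
        (["EEG"] * n_ch, 80),
        (["uV"] * n_ch, 8),
        ([-p for p in pmaxs], 8),
        (pmaxs, 8),
        ([-dig] * n_ch, 8),
        ([dig] * n_ch, 8),
        ([""] * n_ch, 80),
        ([spr] * n_ch, 8),
        ([""] * n_ch, 32),
    ):
        for val in field:
            header += _num(val, width) if isinstance(val, (int, float)) else _ascii(val, width)

    body = bytearray()
    digital = np.empty_like(data, dtype=np.int32)
    for c in range(n_ch):
        gain = pmaxs[c] / dig
        digital[c] = np.clip(np.rint(data[c] / gain), -dig, dig).astype(np.int32)
    for r in range(n_rec):
        chunk = digital[:, r * spr:(r + 1) * spr]
        for c in range(n_ch):
            if kind == "bdf":
                body += _pack24(chunk[c])
            else:
                body += chunk[c].astype("<i2").tobytes()
    Path(path).write_bytes(bytes(header) + bytes(body))


def _pack24(values: np.ndarray) -> bytes:
    v = values.astype(np.int32)
    out = np.empty((v.size, 3), dtype=np.uint8)
    u = v.view(np.uint32) if v.dtype == np.uint32 else v.astype(np.int64) & 0xFFFFFF
    out[:, 0] = u & 0xFF
    out[:, 1] = (u >> 8) & 0xFF
    out[:, 2] = (u >> 16) & 0xFF
    return out.tobytes()


def _unpack24(raw: bytes) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int64)
    v = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
    v[v >= 1 << 23] -= 1 << 24
    return v


def read(path: str | Path) -> tuple[np.ndarray, float, list[str], dict]:
    """Read an EDF/BDF file; returns (μV data, rate, labels, meta)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated header")
    version = raw[:8]
    if version[0] == 0xFF:
        kind = "bdf"
    elif version.strip() == b"0":
        kind = "edf"
    else:
        raise ValueError(f"{path}: unrecognized EDF/BDF version field")

    def text(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", "replace").strip()

    meta = {"subject": text(8, 88), "recording": text(88, 168)}
    n_rec = int(text(236, 244))
    rec_dur = float(text(244, 252))
    n_ch = int(text(252, 256))
    if n_ch <= 0:
        raise ValueError(f"{path}: no channels")
    if rec_dur <= 0:
        raise ValueError(f"{path}: missing record duration (sampling rate)")

    off = 256

    def sig_field(width: int) -> list[str]:
        nonlocal off
        vals = [raw[off + i * width: off + (i + 1) * width]
                .decode("ascii", "replace").strip() for i in range(n_ch)]
        off += width * n_ch
        return vals

    labels = sig_field(16)
    sig_field(80)  # transducer
    sig_field(8)  # dimension
    pmin = [float(v) for v in sig_field(8)]
    pmax = [float(v) for v in sig_field(8)]
    dmin = [int(v) for v in sig_field(8)]
    dmax = [int(v) for v in sig_field(8)]
    sig_field(80)  # prefiltering
    spr = [int(v) for v in sig_field(8)]
    sig_field(32)  # reserved
    if len(set(spr)) != 1:
        raise ValueError(f"{path}: mixed per-signal rates unsupported")
    spr0 = spr[0]
    rate = spr0 / rec_dur

    bps = 3 if kind == "bdf" else 2
    body = raw[256 * (1 + n_ch):]
    expect = n_rec * n_ch * spr0 * bps
    if len(body) < expect:
        raise ValueError(f"{path}: truncated data section")

    data = np.empty((n_ch, n_rec * spr0), dtype=np.float64)
    pos = 0
    for r in range(n_rec):
        for c in range(n_ch):
            raw_sig = body[pos: pos + spr0 * bps]
            pos += spr0 * bps
            if kind == "bdf":
                dig = _unpack24(raw_sig)
            else:
                dig = np.frombuffer(raw_sig, dtype="<i2").astype(np.int64)
            gain = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
            data[c, r * spr0:(r + 1) * spr0] = (dig - dmin[c]) * gain + pmin[c]
    return data, rate, labels, meta
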