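"""Minimal EDF (European Data Format) reader/writer.

Supports the plain (non-EDF+) flavour: a fixed ASCII header, one int16
little-endian data section, identical sampling rate across signals.  The
true sample count is stashed in the reserved header field so that
recordings whose length is not a whole number of records round-trip
without trailing padding.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, data: np.ndarray, fs: float,
              channel_names: list[str], physical_dim: str = "uV",
              recording_id: str = "") -> None:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_sig, n_samples = data.shape
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9 or fs_int <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = fs_int  # one-second records
    n_records = int(np.ceil(n_samples / spr)) if n_samples else 0

    phys_min = data.min(axis=1) if n_samples else np.zeros(n_sig)
    phys_max = data.max(axis=1) if n_samples else np.ones(n_sig)
    # degenerate (constant) channels still need a non-empty physical range
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + _DIG_MIN)
    digital = digital.astype(np.int16)

    pad = n_records * spr - n_samples
    if pad:
        digital = np.pad(digital, ((0, 0), (0, pad)), mode="edge")

    header_bytes = 256 + 256 * n_sig
    with open(path, "wb") as fh:
        fh.write(_fixed("0", 8))
        fh.write(_fixed("X X X X", 80))
        fh.write(_fixed(recording_id, 80))
        fh.write(_fixed("01.01.00", 8))
        fh.write(_fixed("00.00.00", 8))
        fh.write(_fixed(str(header_bytes), 8))
        fh.write(_fixed(f"NSAMP={n_samples}", 44))
        fh.write(_fixed(str(n_records), 8))
        fh.write(_fixed("1", 8))
        fh.write(_fixed(str(n_sig), 4))
        for name in channel_names:
            fh.write(_fixed(name, 16))
        for _ in range(n_sig):
            fh.write(_fixed("", 80))
        for _ in range(n_sig):
            fh.write(_fixed(physical_dim, 8))
        for v in phys_min:
            fh.write(_fixed(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_fixed(f"{v:.8g}"[:8], 8))
        fh.write(_fixed(str(_DIG_MIN), 8) * n_sig)
        fh.write(_fixed(str(_DIG_MAX), 8) * n_sig)
        for _ in range(n_sig):
            fh.write(_fixed("", 80))
        fh.write(_fixed(str(spr), 8) * n_sig)
        fh.write(_fixed("", 32) * n_sig)
        # data records: per record, all samples of signal 0, then signal 1, ...
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.astype("<i2").tobytes())


def read_edf(path: str | Path):
    """Return ``(data, fs, channel_names, recording_id)``."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")

    def f(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii", errors="replace").strip()

    recording_id = f(88, 80)
    reserved = f(192, 44)
    n_records = int(f(236, 8))
    record_dur = float(f(244, 8))
    n_sig = int(f(252, 4))
    off = 256
    names = [f(off + 16 * i, 16) for i in range(n_sig)]
    off += 16 * n_sig + 80 * n_sig + 8 * n_sig  # labels, transducers, dims
    phys_min = np.array([float(f(off + 8 * i, 8)) for i in range(n_sig)])
    off += 8 * n_sig
    phys_max = np.array([float(f(off + 8 * i, 8)) for i in range(n_sig)])
    off += 8 * n_sig
    dig_min = np.array([float(f(off + 8 * i, 8)) for i in range(n_sig)])
    off += 8 * n_sig
    dig_max = np.array([float(f(off + 8 * i, 8)) for i in range(n_sig)])
    off += 8 * n_sig + 80 * n_sig
    spr = [int(f(off + 8 * i, 8)) for i in range(n_sig)]
    off += 8 * n_sig + 32 * n_sig

    if len(set(spr)) != 1:
        raise ValueError(f"{path}: per-signal sampling rates differ")
    fs = spr[0] / record_dur

    payload = np.frombuffer(raw[off:], dtype="<i2")
    expected = n_records * sum(spr)
    if payload.size < expected:
        raise ValueError(f"{path}: truncated EDF data section")
    payload = payload[:expected].reshape(n_records, n_sig, spr[0])
    digital = payload.transpose(1, 0, 2).reshape(n_sig, n_records * spr[0])

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital.astype(float) - dig_min[:, None]) * scale[:, None] + phys_min[:, None]

    if reserved.startswith("NSAMP="):
        n_samples = int(reserved.split("=", 1)[1])
        data = data[:, :n_samples]
    return data, fs, names, recording_id
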