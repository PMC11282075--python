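"""Record loading: one-column CSV or WFDB records, into the unsigned domain.

The codec operates on raw digital ADC integers, never physical millivolts.
Unsigned sources (MIT-BIH's 11-bit records live in [0, 2047]) pass through
unchanged; signed sources (INCART's 16-bit records) are shifted by
``2**(R-1)`` into the unsigned range, with the shift recorded on
``RawRecord.dc_offset`` so the mapping is exactly invertible.

The WFDB support here is a minimal, dependency-free reader covering what
the two target databases use: the single-line-per-signal header dialect,
signal formats 212 (packed 12-bit pairs) and 16 (little-endian int16), and
MIT annotation files for reference beat indices. It is not a general WFDB
implementation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .codec import RawRecord

__all__ = ["load_record", "unmap_samples", "BEAT_ANNOTATION_CODES"]

# MIT annotation codes denoting beats (normal + ectopic + paced families)
BEAT_ANNOTATION_CODES = frozenset(
    [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41]
)


def load_record(
    path: Union[str, Path],
    channel: Union[str, int, None] = None,
    resolution_bits: Optional[int] = None,
) -> RawRecord:
    """Load a record from CSV (+JSON sidecar) or a WFDB header.

    ``channel`` selects a signal by description (e.g. ``"MLII"``) or index;
    by default a lead-II-like channel is preferred, else channel 0.
    ``resolution_bits`` overrides the declared ADC resolution.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _load_csv(path, resolution_bits)
    return _load_wfdb(path, channel, resolution_bits)


def unmap_samples(record: RawRecord) -> np.ndarray:
    """Invert the signed-to-unsigned shift, restoring source digital values."""
    return record.samples.astype(np.int64) - record.dc_offset


# --- CSV -----------------------------------------------------------------


def _load_csv(path: Path, resolution_bits: Optional[int]) -> RawRecord:
    values = np.loadtxt(path, dtype=np.int64, ndmin=1)
    sidecar_path = path.with_suffix(".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    fs = float(meta.get("fs", 360.0))
    bits = resolution_bits or int(meta.get("resolution_bits", 11))
    peaks = meta.get("reference_peaks")
    return _finalize(
        record_id=str(meta.get("record_id", path.stem)),
        fs=fs,
        bits=bits,
        values=values,
        peaks=np.asarray(peaks, dtype=np.int64) if peaks is not None else None,
    )


# --- WFDB ----------------------------------------------------------------


def _load_wfdb(
    path: Path, channel: Union[str, int, None], resolution_bits: Optional[int]
) -> RawRecord:
    header_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header_path.exists():
        raise FileNotFoundError(f"no WFDB header at {header_path}")
    record_line, signal_lines = _parse_header(header_path)
    name, n_sig, fs, n_samples = record_line

    idx = _select_channel(signal_lines, channel)
    sig = signal_lines[idx]
    fmt = sig["format"]

    data_path = header_path.parent / sig["file_name"]
    if fmt == 212:
        all_values = _read_fmt212(data_path, n_sig, n_samples)
    elif fmt == 16:
        all_values = _read_fmt16(data_path, n_sig, n_samples)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    values = all_values[:, idx]

    bits = resolution_bits or sig["adc_res"] or 12
    peaks = None
    ann_path = header_path.with_suffix(".atr")
    if ann_path.exists():
        peaks = _read_annotations(ann_path)
    return _finalize(
        record_id=name, fs=fs, bits=bits, values=values, peaks=peaks
    )


def _parse_header(header_path: Path):
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0

    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        adc_res = int(tok[3]) if len(tok) > 3 else 0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        description = " ".join(tok[8:]) if len(tok) > 8 else ""
        signals.append(
            {
                "file_name": tok[0],
                "format": fmt,
                "adc_res": adc_res,
                "adc_zero": adc_zero,
                "description": description,
            }
        )
    return (name, n_sig, fs, n_samples), signals


def _select_channel(signals, channel: Union[str, int, None]) -> int:
    if isinstance(channel, int):
        if not (0 <= channel < len(signals)):
            raise KeyError(f"channel index {channel} out of range")
        return channel
    if isinstance(channel, str):
        for i, sig in enumerate(signals):
            if sig["description"].lower() == channel.lower():
                return i
        raise KeyError(
            f"channel {channel!r} not found; have "
            f"{[s['description'] for s in signals]}"
        )
    # default preference: a lead-II-like channel, else the first signal
    for i, sig in enumerate(signals):
        if sig["description"].upper() in ("MLII", "II", "LEAD II"):
            return i
    return 0


def _read_fmt16(data_path: Path, n_sig: int, n_samples: int) -> np.ndarray:
    raw = np.fromfile(data_path, dtype="<i2")
    n_frames = raw.size // n_sig
    if n_samples:
        n_frames = min(n_frames, n_samples)
    return raw[: n_frames * n_sig].reshape(n_frames, n_sig).astype(np.int64)


def _read_fmt212(data_path: Path, n_sig: int, n_samples: int) -> np.ndarray:
    """Format 212: two 12-bit two's-complement samples per 3 bytes."""
    raw = np.fromfile(data_path, dtype=np.uint8)
    n_triplets = raw.size // 3
    b = raw[: n_triplets * 3].reshape(-1, 3).astype(np.int64)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    flat = np.empty(2 * n_triplets, dtype=np.int64)
    flat[0::2] = s1
    flat[1::2] = s2
    flat[flat >= 2048] -= 4096  # sign-extend 12-bit values
    n_frames = flat.size // n_sig
    if n_samples:
        n_frames = min(n_frames, n_samples)
    return flat[: n_frames * n_sig].reshape(n_frames, n_sig)


def _read_annotations(ann_path: Path) -> Optional[np.ndarray]:
    """Beat sample indices from an MIT annotation file (beat codes only)."""
    raw = ann_path.read_bytes()
    words = np.frombuffer(
        raw[: len(raw) // 2 * 2], dtype="<u2"
    ).astype(np.int64)
    times: list[int] = []
    t = 0
    i = 0
    while i < words.size:
        word = int(words[i])
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:  # EOF
            break
        if code == 59:  # SKIP: next two words hold a 32-bit interval
            if i + 2 >= words.size:
                break
            t += (int(words[i + 1]) << 16) | int(words[i + 2])
            i += 3
            continue
        if code == 63:  # AUX: interval counts bytes to skip (padded to even)
            i += 1 + (interval + 1) // 2
            continue
        if code in (60, 61, 62):  # NUM/SUB/CHN field changes: no time advance
            i += 1
            continue
        t += interval
        if code in BEAT_ANNOTATION_CODES:
            times.append(t)
        i += 1
    return np.asarray(times, dtype=np.int64) if times else None


# --- shared finalization --------------------------------------------------


def _finalize(
    record_id: str,
    fs: float,
    bits: int,
    values: np.ndarray,
    peaks: Optional[np.ndarray],
) -> RawRecord:
    values = np.asarray(values, dtype=np.int64)
    offset = 0
    if values.size and values.min() < 0:
        offset = 1 << (bits - 1)
        values = values + offset
    if values.size and (values.min() < 0 or values.max() > (1 << bits) - 1):
        raise ValueError(
            f"record {record_id}: values outside declared {bits}-bit range "
            f"after mapping"
        )
    return RawRecord(
        record_id=record_id,
        fs=fs,
        resolution_bits=bits,
        samples=values,
        reference_peaks=peaks,
        dc_offset=offset,
    )
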