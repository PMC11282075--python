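"""Bit-exact `.pwm` container: b-bit codes packed into 64-bit words.

Codes are laid out LSB-first in a contiguous bitstream that is stored as
little-endian 64-bit words; the final word is zero-padded. For b dividing 64
no field straddles a word boundary; for other widths fields run contiguously
across words. Payload size is exactly ``ceil(n*b/64) * 8`` bytes.

A fixed 32-byte header (magic, version, bit widths, rational sampling rate,
sample count, record tag) makes files self-describing; ``raw=True`` writes
bare words for byte-level parity with payload-size accounting.
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .codec import CodecConfig, CompressedStream

__all__ = [
    "MAGIC",
    "PackedHeader",
    "pack",
    "unpack",
    "payload_nbytes",
    "write_pwm",
    "read_pwm",
    "zip_archive",
]

MAGIC = b"PWM1"
_HEADER = struct.Struct("<4sBBBxIIQ8s")  # 32 bytes
VERSION = 1


@dataclass(frozen=True)
class PackedHeader:
    output_bits: int
    input_bits: int
    fs_num: int
    fs_den: int
    n_samples: int
    record_id: str = ""
    version: int = VERSION

    @property
    def fs(self) -> float:
        return self.fs_num / self.fs_den

    def to_bytes(self) -> bytes:
        rid = self.record_id.encode("ascii", "replace")[:8]
        return _HEADER.pack(
            MAGIC,
            self.version,
            self.output_bits,
            self.input_bits,
            self.fs_num,
            self.fs_den,
            self.n_samples,
            rid,
        )

    @classmethod
    def from_bytes(cls, raw: bytes) -> "PackedHeader":
        if len(raw) < _HEADER.size:
            raise ValueError("truncated header")
        magic, version, b, r, fs_num, fs_den, n, rid = _HEADER.unpack(
            raw[: _HEADER.size]
        )
        if magic != MAGIC:
            raise ValueError(f"bad magic {magic!r}")
        return cls(
            output_bits=b,
            input_bits=r,
            fs_num=fs_num,
            fs_den=fs_den,
            n_samples=n,
            record_id=rid.rstrip(b"\x00").decode("ascii", "replace"),
            version=version,
        )


def payload_nbytes(n_samples: int, b: int) -> int:
    """Exact packed payload size: whole 64-bit words."""
    return -(-n_samples * b // 64) * 8


def pack(codes: Sequence[int] | np.ndarray, b: int) -> bytes:
    """Pack unsigned b-bit codes (b in 1..16) into whole little-endian words."""
    if not (1 <= b <= 16):
        raise ValueError("bit width must be in 1..16")
    arr = np.asarray(codes, dtype=np.uint64).ravel()
    if arr.size == 0:
        return b""
    if int(arr.max()) >= (1 << b):
        raise ValueError(f"code exceeds {b}-bit range")
    # per-code bits, LSB first, then one contiguous stream padded to a word
    bits = ((arr[:, None] >> np.arange(b, dtype=np.uint64)) & 1).astype(np.uint8)
    stream = bits.ravel()
    total_bits = payload_nbytes(arr.size, b) * 8
    padded = np.zeros(total_bits, dtype=np.uint8)
    padded[: stream.size] = stream
    return np.packbits(padded, bitorder="little").tobytes()


def unpack(payload: bytes, b: int, n_samples: int) -> np.ndarray:
    """Inverse of :func:`pack`; validates the exact whole-word payload length."""
    if not (1 <= b <= 16):
        raise ValueError("bit width must be in 1..16")
    expected = payload_nbytes(n_samples, b)
    if len(payload) != expected:
        raise ValueError(
            f"payload is {len(payload)} bytes; expected {expected} for "
            f"{n_samples} samples at {b} bits"
        )
    if n_samples == 0:
        return np.empty(0, dtype=np.uint16)
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8), bitorder="little")
    bits = bits[: n_samples * b].reshape(n_samples, b).astype(np.uint32)
    weights = (1 << np.arange(b, dtype=np.uint32)).astype(np.uint32)
    return (bits * weights).sum(axis=1).astype(np.uint16)


def write_pwm(path, stream: CompressedStream, *, raw: bool = False) -> int:
    """Write a compressed stream to disk; returns bytes written."""
    payload = pack(stream.codes, stream.config.output_bits)
    blob = payload
    if not raw:
        frac = Fraction(stream.fs).limit_denominator(10**6)
        header = PackedHeader(
            output_bits=stream.config.output_bits,
            input_bits=stream.config.input_bits,
            fs_num=frac.numerator,
            fs_den=frac.denominator,
            n_samples=stream.n_samples,
            record_id=stream.record_id,
        )
        blob = header.to_bytes() + payload
    Path(path).write_bytes(blob)
    return len(blob)


def read_pwm(path) -> CompressedStream:
    """Read a headered `.pwm` file back into a :class:`CompressedStream`."""
    raw = Path(path).read_bytes()
    header = PackedHeader.from_bytes(raw)
    payload = raw[_HEADER.size :]
    codes = unpack(payload, header.output_bits, header.n_samples)
    config = CodecConfig(
        input_bits=header.input_bits, output_bits=header.output_bits
    )
    return CompressedStream(
        codes=codes,
        config=config,
        fs=header.fs,
        n_samples=header.n_samples,
        final_acc=0,
        record_id=header.record_id,
    )


def zip_archive(paths: Iterable, out_path) -> int:
    """Deflate-archive already-packed files (convenience; level 5).

    Thin glue over the standard ZIP format for the extra archival pass some
    deployments layer on top of the packed container. Returns archive size
    in bytes.
    """
    out_path = Path(out_path)
    with zipfile.ZipFile(
        out_path, "w", compression=zipfile.ZIP_DEFLATED, compresslevel=5
    ) as zf:
        for p in paths:
            zf.write(p, arcname=Path(p).name)
    return out_path.stat().st_size
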