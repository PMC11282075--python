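"""Synthetic ECG generator with exact R-peak ground truth.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed at fixed
offsets from the R-wave center; beat-to-beat R-R intervals are Gaussian
around ``60 / mean_hr`` (truncated at 0.3 s) and R centers are snapped to
the sample grid so the recorded reference peaks are exact. Optional white
noise and sinusoidal baseline wander corrupt the trace; everything rides on
an unsigned baseline and clips to the declared ADC range.

Defaults emulate an MIT-BIH-style lead-II acquisition: 360 Hz, 11-bit,
baseline at mid-range (1024 counts), 70 bpm with mild sinus variability,
R amplitude ~1.5 mV at the database's nominal 200 counts/mV gain. The model
covers rhythm and gross morphology only — no arrhythmic beats, pacemaker
artefacts, electrode motion or morphology drift — so results on it bound
codec behaviour on clean signals, not detector robustness on pathology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .codec import RawRecord

__all__ = ["WaveParams", "SynthConfig", "generate_record", "write_csv", "write_wfdb"]


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian component: amplitude (ADC counts), sigma (s), R offset (s)."""

    amplitude: float
    width_s: float
    offset_s: float


def _default_waves() -> dict[str, WaveParams]:
    # lead-II-plausible morphology at 200 counts/mV
    return {
        "P": WaveParams(amplitude=40.0, width_s=0.025, offset_s=-0.160),
        "Q": WaveParams(amplitude=-60.0, width_s=0.010, offset_s=-0.030),
        "R": WaveParams(amplitude=300.0, width_s=0.012, offset_s=0.0),
        "S": WaveParams(amplitude=-80.0, width_s=0.010, offset_s=0.030),
        "T": WaveParams(amplitude=90.0, width_s=0.060, offset_s=0.300),
    }


@dataclass
class SynthConfig:
    duration_s: float = 60.0
    fs: float = 360.0
    resolution_bits: int = 11
    baseline: Optional[int] = None  # defaults to mid-range 2**(R-1)
    mean_hr_bpm: float = 70.0
    hr_sd_bpm: float = 3.0
    wave_params: dict[str, WaveParams] = field(default_factory=_default_waves)
    noise_sd: float = 0.0
    baseline_wander: tuple[float, float] = (0.0, 0.0)  # (amplitude counts, Hz)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.mean_hr_bpm <= 0:
            raise ValueError("heart rate must be positive")

    @property
    def baseline_counts(self) -> int:
        if self.baseline is not None:
            return self.baseline
        return 1 << (self.resolution_bits - 1)


def generate_record(config: SynthConfig) -> RawRecord:
    """Render a record; ``reference_peaks`` hold the exact R-center indices."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    mean_rr = 60.0 / config.mean_hr_bpm
    # convert HR spread to an R-R spread around the operating point
    rr_sd = 60.0 * config.hr_sd_bpm / config.mean_hr_bpm**2

    beat_times: list[float] = []
    t_beat = 0.5 * mean_rr  # first beat partway into the record
    margin = 0.45  # leave room for the trailing T wave
    while t_beat < config.duration_s - margin:
        beat_times.append(round(t_beat * fs) / fs)  # snap R center to the grid
        rr = rng.normal(mean_rr, rr_sd) if rr_sd > 0 else mean_rr
        t_beat += max(rr, 0.3)

    x = np.zeros(n, dtype=float)
    span = 0.45  # render each beat only inside a local window
    for tb in beat_times:
        lo = max(0, int((tb - span) * fs))
        hi = min(n, int((tb + span) * fs) + 1)
        tt = t[lo:hi]
        for wave in config.wave_params.values():
            x[lo:hi] += wave.amplitude * np.exp(
                -((tt - tb - wave.offset_s) ** 2) / (2.0 * wave.width_s**2)
            )

    amp_w, freq_w = config.baseline_wander
    if amp_w and freq_w:
        x += amp_w * np.sin(2.0 * np.pi * freq_w * t)
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=n)

    full_scale = (1 << config.resolution_bits) - 1
    samples = np.clip(
        np.rint(x + config.baseline_counts), 0, full_scale
    ).astype(np.int64)
    peaks = np.asarray([int(round(tb * fs)) for tb in beat_times], dtype=np.int64)

    return RawRecord(
        record_id=f"synth-{config.seed}",
        fs=fs,
        resolution_bits=config.resolution_bits,
        samples=samples,
        reference_peaks=peaks,
    )


def write_csv(record: RawRecord, path) -> Path:
    """One-column integer CSV plus a JSON sidecar carrying fs/resolution/peaks."""
    path = Path(path)
    np.savetxt(path, record.samples, fmt="%d")
    sidecar = {
        "record_id": record.record_id,
        "fs": record.fs,
        "resolution_bits": record.resolution_bits,
    }
    if record.reference_peaks is not None:
        sidecar["reference_peaks"] = [int(p) for p in record.reference_peaks]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def write_wfdb(record: RawRecord, directory, *, channel_name: str = "MLII") -> Path:
    """Emit a WFDB-compatible record: header, format-16 signal, annotations.

    The signal file stores the raw digital values as little-endian int16
    (WFDB format 16); reference peaks, when present, become a standard MIT
    annotation file of normal beats. Round-trips through
    :func:`pwmecg.ingest.load_record`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    n = record.samples.size

    adc_zero = 0
    first = int(record.samples[0]) if n else 0
    header = (
        f"{name} 1 {record.fs:g} {n}\n"
        f"{name}.dat 16 200 {record.resolution_bits} {adc_zero} {first} 0 0 "
        f"{channel_name}\n"
    )
    (directory / f"{name}.hea").write_text(header)
    record.samples.astype("<i2").tofile(directory / f"{name}.dat")

    if record.reference_peaks is not None:
        (directory / f"{name}.atr").write_bytes(
            _encode_annotations(record.reference_peaks)
        )
    return directory / f"{name}.hea"


def _encode_annotations(peaks: np.ndarray) -> bytes:
    """MIT annotation stream of NORMAL (code 1) beats at the given indices."""
    out = bytearray()
    prev = 0
    for p in peaks:
        delta = int(p) - prev
        if delta > 1023:  # long gaps carried by a SKIP record (32-bit interval)
            out += (59 << 10).to_bytes(2, "little")
            out += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        out += ((1 << 10) | delta).to_bytes(2, "little")
        prev = int(p)
    out += (0).to_bytes(2, "little")  # EOF
    return bytes(out)
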