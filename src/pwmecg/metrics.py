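"""Reconstruction-quality and clinical-utility metrics.

Signal-level scores:

* ``PRD = 100 * sqrt(sum((x - xhat)^2) / sum(x^2))`` — percentage
  root-mean-square difference between original and reconstruction.
* ``BCR = N_o / N_r`` — bit compression ratio. By convention an original
  11-bit sample occupies 16 bits (2 bytes) in byte-aligned storage, so
  ``N_o = 16`` unless stated otherwise.
* ``QS = BCR / PRD`` — quality score (infinite for a perfect reconstruction).
* ``space saving = (1 - F_r / F_o) * 100%`` on actual byte counts.

Utility scores compare beat detections: greedy one-to-one matching within a
tolerance window yields TP/FP/FN, from which sensitivity
``SE = TP/(TP+FN)`` and positive precision ``+P = TP/(TP+FP)`` follow. The
heart-rate-variability error HV is the mean absolute difference, over
consecutive one-minute windows, of the within-window average R-R interval
(in samples) between two detection streams.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MatchResult",
    "EvaluationReport",
    "prd",
    "compression_summary",
    "match_beats",
    "detection_stats",
    "hrv_error",
    "DEFAULT_MATCH_TOLERANCE_MS",
]

# ANSI/AAMI-style beat-match window (+-150 ms; 54 samples at 360 Hz)
DEFAULT_MATCH_TOLERANCE_MS = 150.0


def prd(original, reconstructed) -> float:
    """Percentage RMS difference; scale-invariant and zero iff identical."""
    x = np.asarray(original, dtype=float)
    xh = np.asarray(reconstructed, dtype=float)
    if x.shape != xh.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {xh.shape}")
    if x.size == 0:
        raise ValueError("empty signals")
    denom = float(np.sum(x * x))
    if denom == 0.0:
        raise ValueError("PRD undefined for an all-zero original signal")
    return 100.0 * math.sqrt(float(np.sum((x - xh) ** 2)) / denom)


@dataclass(frozen=True)
class CompressionSummary:
    bcr: float
    qs: float
    space_saving: float


def compression_summary(
    n_bits_original_storage: int,
    n_bits_compressed: int,
    prd_percent: float,
    bytes_before: int,
    bytes_after: int,
) -> CompressionSummary:
    """BCR, QS and space saving from bit widths, PRD and actual byte counts.

    ``qs`` is ``inf`` when PRD is exactly zero (flagged, not an error: a
    perfect reconstruction has unbounded quality per the ratio definition).
    """
    if n_bits_original_storage <= 0 or n_bits_compressed <= 0:
        raise ValueError("bit counts must be positive")
    if bytes_before <= 0 or bytes_after <= 0:
        raise ValueError("byte counts must be positive")
    if prd_percent < 0:
        raise ValueError("PRD cannot be negative")
    bcr = n_bits_original_storage / n_bits_compressed
    qs = math.inf if prd_percent == 0 else bcr / prd_percent
    saving = (1.0 - bytes_after / bytes_before) * 100.0
    return CompressionSummary(bcr=bcr, qs=qs, space_saving=saving)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)


def match_beats(reference, detected, tolerance: int) -> MatchResult:
    """Greedy one-to-one nearest matching of detections to reference beats.

    Candidate (reference, detection) pairs within ``+-tolerance`` samples are
    taken in order of increasing distance, each beat used at most once.
    Unmatched detections are false positives; unmatched references, false
    negatives.
    """
    ref = np.asarray(reference, dtype=np.int64)
    det = np.asarray(detected, dtype=np.int64)
    for name, a in (("reference", ref), ("detected", det)):
        if a.size > 1 and np.any(np.diff(a) <= 0):
            raise ValueError(f"{name} indices must be strictly increasing")

    candidates: list[tuple[int, int, int]] = []
    j0 = 0
    for i, r in enumerate(ref):
        # advance past detections left of the window, then scan the window
        while j0 < det.size and det[j0] < r - tolerance:
            j0 += 1
        j = j0
        while j < det.size and det[j] <= r + tolerance:
            candidates.append((abs(int(det[j]) - int(r)), i, j))
            j += 1
    candidates.sort()

    ref_used = np.zeros(ref.size, dtype=bool)
    det_used = np.zeros(det.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if not ref_used[i] and not det_used[j]:
            ref_used[i] = True
            det_used[j] = True
            pairs.append((int(ref[i]), int(det[j])))
    pairs.sort()
    tp = len(pairs)
    return MatchResult(tp=tp, fp=det.size - tp, fn=ref.size - tp, matched_pairs=pairs)


def detection_stats(m: MatchResult) -> tuple[float, float]:
    """Sensitivity and positive precision, in percent.

    Empty denominators yield NaN flags rather than raising: a record with no
    reference beats has undefined sensitivity, and one with no detections
    has undefined precision — except the fully-degenerate-but-consistent
    zero case, reported as 0.
    """
    se = 100.0 * m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else math.nan
    plus_p = 100.0 * m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else math.nan
    return se, plus_p


def hrv_error(
    ref_peaks, rec_peaks, fs: float
) -> tuple[float, list[Optional[float]]]:
    """Per-minute mean R-R interval error between two peak streams.

    The record is split into consecutive non-overlapping ``fs * 60``-sample
    windows anchored at sample 0; a beat belongs to the window containing
    its R index. Within each window the R-R intervals between consecutive
    in-window beats are averaged separately for the two streams; the window
    error is the absolute difference of those averages. Windows with fewer
    than two beats in either stream contribute ``None`` (skipped). HV is the
    mean over the valid windows (NaN if none are valid).
    """
    ref = np.asarray(ref_peaks, dtype=np.int64)
    rec = np.asarray(rec_peaks, dtype=np.int64)
    window = int(round(fs * 60))
    if window <= 0:
        raise ValueError("sampling rate must be positive")
    last = max(
        int(ref[-1]) if ref.size else 0,
        int(rec[-1]) if rec.size else 0,
    )
    n_windows = last // window + 1 if (ref.size or rec.size) else 0

    def window_mean_rr(peaks: np.ndarray, w: int) -> Optional[float]:
        inside = peaks[(peaks >= w * window) & (peaks < (w + 1) * window)]
        if inside.size < 2:
            return None
        return float(np.diff(inside).mean())

    errors: list[Optional[float]] = []
    for w in range(n_windows):
        a = window_mean_rr(ref, w)
        b = window_mean_rr(rec, w)
        errors.append(None if a is None or b is None else abs(a - b))
    valid = [e for e in errors if e is not None]
    hv = float(np.mean(valid)) if valid else math.nan
    return hv, errors


@dataclass
class EvaluationReport:
    """One record's full scorecard, with the settings that produced it."""

    record_id: str
    bits: int
    prd: float
    bcr: float
    qs: float
    space_saving: float
    per_detector: dict[str, tuple[float, float]] = field(default_factory=dict)
    hv: float = math.nan
    hv_skipped_windows: int = 0
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "bits": self.bits,
            "prd_percent": self.prd,
            "bcr": self.bcr,
            "qs": None if math.isinf(self.qs) else self.qs,
            "space_saving_percent": self.space_saving,
            "per_detector": {
                k: {"se_percent": v[0], "plus_p_percent": v[1]}
                for k, v in self.per_detector.items()
            },
            "hv_samples": None if math.isnan(self.hv) else self.hv,
            "hv_skipped_windows": self.hv_skipped_windows,
            "metadata": self.metadata,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_table(self) -> str:
        lines = [
            f"record        : {self.record_id}",
            f"bits          : {self.bits}",
            f"PRD           : {self.prd:.4f} %",
            f"BCR           : {self.bcr:.3f}",
            f"QS            : {'inf' if math.isinf(self.qs) else f'{self.qs:.3f}'}",
            f"space saving  : {self.space_saving:.2f} %",
        ]
        for name, (se, pp) in self.per_detector.items():
            lines.append(f"{name:<14}: SE {se:.2f} %, +P {pp:.2f} %")
        hv = "n/a" if math.isnan(self.hv) else f"{self.hv:.3f} samples"
        lines.append(f"HV            : {hv} ({self.hv_skipped_windows} windows skipped)")
        return "\n".join(lines)
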