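"""Pan-Tompkins-style R-peak detection, plus a plug-in detector registry.

The built-in detector follows the classic energy pipeline: band-pass the
signal to the 5-15 Hz QRS band, differentiate, square, integrate over a
150 ms moving window, and pick peaks of the integrated energy with adaptive
signal/noise thresholds and a 200 ms refractory period. Peak positions are
refined to the band-passed R-wave maximum, so indices land in the original
sample frame (all filtering is zero-phase, so no delay compensation is
needed).

External detectors (e.g. the XQRS, Elgendi and Hamilton implementations
from other packages) can be registered through :func:`register_detector`;
any callable ``(values, fs) -> sorted indices`` qualifies. Entries for the
usual suspects self-register when the providing package is importable.
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np
from scipy import signal as sps

__all__ = [
    "detect_r_peaks",
    "register_detector",
    "get_detector",
    "available_detectors",
    "REFRACTORY_S",
]

REFRACTORY_S = 0.200
_INTEGRATION_S = 0.150
_BAND_HZ = (5.0, 15.0)


def detect_r_peaks(values, fs: float) -> np.ndarray:
    """Detect R-peak sample indices in a single-channel ECG.

    Requires at least two seconds of signal (the adaptive thresholds need a
    learning window). A flat signal yields no detections. Output is strictly
    increasing with gaps of at least the refractory period, deterministic,
    and invariant to positive rescaling of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal for R-peak detection")
    if np.ptp(x) == 0:
        return np.empty(0, dtype=np.int64)

    # 5-15 Hz band isolates QRS energy; zero-phase keeps peaks aligned
    nyq = fs / 2.0
    hi = min(_BAND_HZ[1], 0.9 * nyq)
    sos = sps.butter(2, [_BAND_HZ[0], hi], btype="band", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)

    # five-point derivative emphasises slope, squaring rectifies
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(band, kernel[::-1], mode="same")
    energy = deriv * deriv

    win = max(1, int(round(_INTEGRATION_S * fs)))
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.empty(0, dtype=np.int64)

    # adaptive signal/noise running estimates seeded from a 2 s learning phase
    learn = mwi[: int(2 * fs)]
    spk = float(learn.max()) * 0.5
    npk = float(learn.mean()) * 0.5
    accepted: list[int] = []
    for c in cand:
        peak = float(mwi[c])
        threshold = npk + 0.25 * (spk - npk)
        if peak > threshold:
            spk = 0.125 * peak + 0.875 * spk
            accepted.append(int(c))
        else:
            npk = 0.125 * peak + 0.875 * npk
    if not accepted:
        return np.empty(0, dtype=np.int64)

    # refine each energy peak to the R-wave maximum in the band-passed frame
    half = int(round(0.10 * fs))
    refined: list[int] = []
    for c in accepted:
        lo, hi_ = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(band[lo:hi_])))

    # dedupe and re-impose the refractory gap after refinement
    out: list[int] = []
    for r in sorted(set(refined)):
        if out and r - out[-1] < refractory:
            if band[r] > band[out[-1]]:
                out[-1] = r
            continue
        out.append(r)
    return np.asarray(out, dtype=np.int64)


_REGISTRY: Dict[str, Callable] = {"pan_tompkins": detect_r_peaks}


def register_detector(name: str, fn: Callable) -> None:
    """Register a callable ``(values, fs) -> sorted indices`` under a name."""
    if not callable(fn):
        raise TypeError("detector must be callable")
    _REGISTRY[name] = fn


def get_detector(name: str) -> Callable:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown detector {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_detectors() -> list[str]:
    return sorted(_REGISTRY)


def _register_external_detectors() -> None:
    # Optional plug-ins; silently absent when the packages are not installed.
    try:  # wfdb's XQRS
        from wfdb import processing as _wp  # type: ignore

        def _xqrs(values, fs):
            out = _wp.xqrs_detect(
                sig=np.asarray(values, dtype=float), fs=fs, verbose=False
            )
            return np.asarray(out, dtype=np.int64)

        register_detector("xqrs", _xqrs)
    except ImportError:
        pass
    try:  # py-ecg-detectors
        from ecgdetectors import Detectors as _Detectors  # type: ignore

        def _make(method_name):
            def _run(values, fs):
                det = _Detectors(fs)
                out = getattr(det, method_name)(np.asarray(values, dtype=float))
                return np.asarray(sorted(out), dtype=np.int64)

            return _run

        register_detector("elgendi", _make("two_average_detector"))
        register_detector("hamilton", _make("hamilton_detector"))
        register_detector("pan_tompkins_ext", _make("pan_tompkins_detector"))
    except ImportError:
        pass


_register_external_detectors()
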