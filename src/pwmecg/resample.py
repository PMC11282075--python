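"""Plain linear-interpolation resampling of code streams.

Down-sampling the code stream (e.g. 360 -> 180 or 120 Hz) trades fidelity
for a proportional cut in stored points. No anti-aliasing filter precedes
the interpolation: the resampler is deliberately just linear interpolation
on the sample-time grid. The inverse (up-sampling back to the original rate)
uses the same primitive, so evaluation of a down-sampled stream can score
against the full-rate original.
"""

from __future__ import annotations

import numpy as np

from .codec import CodecConfig, CompressedStream

__all__ = ["resample_linear", "resample_stream"]


def resample_linear(values, fs_in: float, fs_out: float) -> np.ndarray:
    """Resample to times ``k / fs_out`` covering the input duration.

    ``fs_out == fs_in`` returns the values unchanged. Output sample ``k`` is
    the linear interpolation of the two input samples bracketing time
    ``k / fs_out``; the output grid spans ``[0, (n-1)/fs_in]``.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(values, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    if x.size < 2:
        raise ValueError("need at least 2 samples to resample to a new rate")
    n_out = int(np.floor((x.size - 1) * fs_out / fs_in)) + 1
    t_in = np.arange(x.size) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, x)


def resample_stream(stream: CompressedStream, fs_out: float) -> CompressedStream:
    """Resample a code stream, re-quantizing interpolated codes to integers.

    Interpolated values are rounded half-up and clipped back into
    ``[0, 2**b - 1]`` so the result is a valid packable code stream at the
    new rate.
    """
    if fs_out == stream.fs:
        return stream
    values = resample_linear(stream.codes.astype(float), stream.fs, fs_out)
    codes = np.clip(
        np.floor(values + 0.5).astype(np.int64), 0, stream.config.max_code
    ).astype(np.uint16)
    return CompressedStream(
        codes=codes,
        config=stream.config,
        fs=fs_out,
        n_samples=codes.size,
        final_acc=stream.final_acc,
        record_id=stream.record_id,
    )
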