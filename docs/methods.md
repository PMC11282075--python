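# Methods

## Compression model

The codec is an error-feedback (sigma-delta-like) quantizer on unsigned
integer ADC samples. With input resolution R bits and output resolution b
bits (1 ≤ b < R ≤ 16), the step size is `S = 2^(R−b)` counts. Per sample:
floor-quantize to the S-grid, add the truncation error `e ∈ [0, S−1]` to a
running accumulator, and when the accumulator strictly exceeds S, emit one
level higher and subtract S from the accumulator. The emitted b-bit code is
the level index. Assumptions: the source is unsigned (signed sources are
shifted, see Ingest), stationary enough that a 27 Hz low-pass recovers the
duty-cycle average, and sampled fast relative to the signal bandwidth so
the level toggling is far above the signal band.

Three choices close gaps the behavioural description leaves open, and each
is forced by an invariant:

* **Fire on strict `acc > S`**, keeping "unchanged when ≤ S" exact.
* **Subtract S when firing.** This is the only update that (a) bounds the
  accumulator to `[0, S]` on non-clamped paths and (b) yields prefix
  conservation `Σx − S·Σcode = acc_n − acc_0`, i.e. the PWM duty cycle
  carries the running average. Both are property-tested, and the kernel is
  checked exhaustively over all `(x, acc)` states at R=4 against a
  brute-force reference written from the behavioural description.
* **Top-code clamp.** If an injection would exceed code `2^b − 1`, the code
  saturates and the step returns to the accumulator, itself saturating at
  `2S`. Unclamped overflow would corrupt the packed container; saturation
  bounds the error a pathological run of full-scale samples can defer.

Floor (truncating) division keeps the error non-negative, so the
accumulator needs no sign bit; the worst-case path costs 3 scaling
(÷, ×) and 6 basic (−, +, <) integer operations, which an instrumented
twin of the kernel verifies by exhaustive walk (the rare clamp body is
excluded from the budget; its guard comparison is counted).

## Reconstruction

Codes are upscaled by S and passed through a digital 3rd-order Butterworth
low-pass at 27 Hz, designed by bilinear transform with cutoff pre-warping
(scipy). The analog magnitude prototype is
`|H(jω)|² = 1/(1 + (ω/ω_c)^(2N))`; we implement the standard N=3 transfer
function whose squared magnitude matches it. Two application modes:

* `zero_phase` (default for evaluation): forward-backward filtering.
  Zero net phase — cross-correlation lag against a clean input is 0
  samples — at the cost of squaring the magnitude response (gain 1/2 at
  cutoff instead of 1/√2). A causal 27 Hz pass adds ~4 samples of group
  delay at 360 Hz and materially inflates PRD, so offline scoring uses
  zero-phase; both modes ship.
* `causal`: single forward pass, initialized to the steady state of the
  first sample so a signal riding a 1024-count baseline does not see a
  start-up transient.

DC gain is exactly 1 in both modes (sum-of-coefficients identity).

## Resampling

Optional further compression linearly interpolates the code stream to
180 or 120 Hz (output grid `k/fs_out` over the input duration), halving or
thirding stored points. No anti-aliasing filter precedes it — the
resampler is deliberately bare linear interpolation. Interpolated codes
are rounded half-up and clipped back into `[0, 2^b−1]` so the result packs
like any code stream. A down-sampled stream is reconstructed at its own
rate with the same 27 Hz cutoff, then linearly up-sampled to the original
rate before PRD/detection scoring; the report metadata records this.

## Storage

Codes pack LSB-first into little-endian 64-bit words; payload size is
exactly `⌈n·b/64⌉ × 8` bytes (a 650,000-sample record at b=4 → 325,000
bytes). For b ∈ {1,2,4,8,16} no field straddles a word; other widths run
contiguously. A 32-byte self-describing header (magic, version, b, R,
rational fs, n, record tag) precedes the payload; `raw` mode omits it for
byte-level parity with the size formula. A thin zipfile wrapper (deflate,
level 5) reproduces the optional archival pass. Space saving is reported
against the 16-bit (2 bytes/sample) byte-aligned storage convention for
the original; absolute savings against any particular database folder
depend on that folder's composition and are not reproduced.

## Metrics and protocols

PRD, BCR (N_o = 16 by the byte-aligned convention, not the nominal 11),
QS = BCR/PRD (infinite-flagged at PRD 0), and space saving on actual byte
counts. Beat matching is greedy one-to-one nearest within ±150 ms (54
samples at 360 Hz — the common ANSI/AAMI-style window), from which
SE and +P follow. The HV statistic partitions the record into
non-overlapping `fs×60`-sample windows anchored at sample 0, averages the
R–R intervals of consecutive in-window beats separately per stream, and
takes the mean absolute difference over windows with ≥ 2 beats in both
streams; sparser windows are skipped and counted in the report. HV in the
pipeline compares detector output on the original versus the
reconstructed signal, so HV = 0 whenever reconstruction preserves every
detected R index.

## QRS detection

The built-in detector follows the classic Pan-Tompkins energy pipeline:
5–15 Hz band-pass (2nd-order Butterworth, zero-phase), five-point
derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise thresholds (0.125/0.875 running updates, threshold =
noise + 0.25·(signal − noise), seeded from a 2 s learning window) with a
200 ms refractory period, and refinement of each energy peak to the
band-passed R maximum within ±100 ms. Zero-phase filtering makes delay
compensation unnecessary; relative thresholds make detection invariant to
positive rescaling. External detectors (XQRS, Elgendi, Hamilton) plug in
through the registry as `(values, fs) → sorted indices` callables and
self-register when their packages are importable; published benchmark
numbers for those detectors depend on their exact implementations, so the
internal detector carries the self-contained tests.

## Synthetic records

The fixture generator renders each beat as five Gaussian waves at fixed
offsets from the R center (defaults, in ADC counts at the MIT-BIH-nominal
200 counts/mV: P +40/σ25 ms/−160 ms, Q −60/10/−30, R +300/12/0,
S −80/10/+30, T +90/60/+300), on a mid-range baseline (1024 at 11 bits),
at 360 Hz. R–R intervals are Gaussian around 60/HR (default 70 bpm, SD
3 bpm, truncated at 0.3 s) with R centers snapped to the sample grid so
`reference_peaks` are exact. Optional white noise and sinusoidal baseline
wander are off by default. A Gaussian-wave model was chosen over a
dynamical-system generator: it is simpler, fully seeded-reproducible, and
sufficient to exercise quantization, filtering, packing, detection and HV
logic. It does **not** emulate arrhythmic morphology, pacemaker artefacts,
electrode motion or beat-to-beat morphology drift, so passing scores on it
demonstrate codec correctness on clean signals, not detector robustness on
pathology.

## Ingest

Compression operates on raw digital ADC integers (the integer-only
operation budget requires it), never physical millivolts. One-column CSV
(with a JSON sidecar for fs/resolution/reference peaks) and a minimal,
dependency-free WFDB reader are provided: single-line header dialect,
signal formats 212 (packed 12-bit pairs) and 16 (little-endian int16), and
MIT annotation files for beat indices, with lead II preferred by default.
Unsigned sources (MIT-BIH's [0, 2047]) pass through unchanged; sources
containing negative values (INCART's signed 16-bit) are shifted by
`+2^(R−1)`, with the shift kept on the record so unmapping is exact.

## Problem sizes and numerical choices

Self-contained tests and the acceptance script use 60 s synthetic records
(21,600 samples) — long enough for at least one full HV window and ~70
beats, and representative since every pipeline stage is O(n) and
state-local. Exhaustive kernel checks run at R=4 (all 16×(2S+1) states per
b), where equivalence to the brute-force reference is a complete proof of
the integer kernel for that configuration and the arithmetic is
width-independent. Tolerances: the cutoff-magnitude test allows 2% for
the bilinear design's departure from the analog closed form, measured on
central cycles clear of edge transients; everything integer (codes,
packing, accumulator) is asserted exactly. Ties in beat matching resolve
by smallest distance, then earliest reference. Degenerate inputs: empty
streams are valid everywhere except metrics that would divide by zero,
which raise or flag (NaN/inf) as documented.

## Known limitations

* The benchmark protocol over the public arrhythmia databases (per-record
  PRD/SE/+P/HV tables, pacemaker-record exclusion) is fully implemented
  but only exercised here on synthetic WFDB directories; real-database
  figures require the PhysioNet downloads.
* The WFDB reader covers exactly the header/signal/annotation subset the
  two target databases use; it is not a general implementation.
* The causal reconstruction path is provided for streaming parity but the
  reported scores use zero-phase filtering; a real-time deployment would
  see the causal group delay.
* BCR reflects the bit-width convention, not entropy: the codes are not
  entropy-coded (the optional ZIP pass is external archival, not part of
  the codec).
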