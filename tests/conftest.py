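import numpy as np
import pytest

from pwmecg.synth import SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """60 s clean synthetic 11-bit/360 Hz record, 70 bpm, exact R ground truth."""
    return generate_record(SynthConfig(duration_s=60.0, seed=42))


@pytest.fixture(scope="session")
def noisy_record():
    """Same conditions plus white noise at 20 dB SNR (relative to AC power)."""
    clean = generate_record(SynthConfig(duration_s=60.0, seed=42))
    ac = clean.samples.astype(float) - float(np.mean(clean.samples))
    noise_sd = float(np.sqrt(np.mean(ac**2) / 10.0**(20.0 / 10.0)))
    return generate_record(SynthConfig(duration_s=60.0, seed=42, noise_sd=noise_sd))
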