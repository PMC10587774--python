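import numpy as np
import pytest

from hfoprime import synth
from hfoprime.config import AnalysisConfig, SynthConfig


@pytest.fixture(scope="session")
def acfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_recording():
    """One rendered 2-channel, 2-minute recording with ground truth."""
    cfg = SynthConfig(n_contacts_per_patient=2, recording_minutes=2.0,
                      snr_db=15.0, seed=11)
    rec, truth = synth.gen_ieeg(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def pink_record():
    """Event-free pink-noise record for false-positive / invariance checks."""
    fs = 2000.0
    n = int(fs * 120)
    rng = np.random.default_rng(5)
    x = 25 * synth._pink_noise(n, rng) \
        + 50 * np.sin(2 * np.pi * 1.0 * np.arange(n) / fs)
    from hfoprime.io import IEEGRecording
    return IEEGRecording(samples=x[None, :], fs=fs, channel_labels=["c00"])


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    cfg = SynthConfig(n_patients=2, n_contacts_per_patient=2,
                      recording_minutes=1.0, seed=21)
    out = tmp_path_factory.mktemp("cohort")
    synth.gen_cohort(cfg, out)
    return cfg, out
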