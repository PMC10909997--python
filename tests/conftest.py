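import numpy as np
import pytest
from hypothesis import settings

from hrvdt.synth import AutonomicParams, NoiseSpec, gen_ecg, gen_rr_series

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def modulated_rr():
    """300 s IPFM series with both LF and HF modulation and mild jitter."""
    return gen_rr_series(
        AutonomicParams(mean_rr=800, a_lf=0.05, a_hf=0.05, jitter_sd=5, seed=3),
        duration=300.0)


@pytest.fixture(scope="session")
def short_rr():
    """60 s series for quick structural checks."""
    return gen_rr_series(AutonomicParams(seed=7), duration=60.0)


@pytest.fixture(scope="session")
def clean_ecg(short_rr):
    """Noise-free synthetic ECG with ground-truth annotations."""
    return gen_ecg(short_rr, fs=256.0, noise=NoiseSpec())


def match_beats(detected, annotated, tol_s=0.020):
    """Sensitivity and positive predictivity under +-tol matching."""
    detected, annotated = np.asarray(detected), np.asarray(annotated)
    if len(detected) == 0 or len(annotated) == 0:
        return 0.0, 0.0
    d = np.abs(detected[:, None] - annotated[None, :])
    sens = float(np.mean(d.min(axis=0) <= tol_s))
    ppv = float(np.mean(d.min(axis=1) <= tol_s))
    return sens, ppv


@pytest.fixture(scope="session")
def beat_matcher():
    return match_beats
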