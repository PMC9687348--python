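import numpy as np
import pytest

from axisppg.model import ModelConfig
from axisppg.synthetic import SyntheticSpec, synthesize_face_video


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale network configuration used across model tests."""
    return ModelConfig(T=8, size=16, mixer_case=6, seed=0)


@pytest.fixture(scope="session")
def clean_clip():
    """Noise-free, jitter-free clip: the planted signal is exactly affine."""
    spec = SyntheticSpec(hr_bpm=72, hrv_sd=0.0, fps=20, duration_s=5,
                         height=32, width=32, noise_sd=0.0,
                         motion_jitter_px=0, illum_drift_amp=0.0, seed=7)
    return synthesize_face_video(spec)
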