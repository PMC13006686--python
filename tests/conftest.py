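import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

FS = 500.0


@pytest.fixture
def fs() -> float:
    return FS


@pytest.fixture
def sine():
    """Factory for sampled sinusoids: sine(freq, amp, duration)."""

    def make(freq_hz: float, amp_uv: float = 100.0, duration_s: float = 60.0,
             fs: float = FS, phase: float = 0.0) -> np.ndarray:
        t = np.arange(int(round(duration_s * fs))) / fs
        return amp_uv * np.sin(2 * np.pi * freq_hz * t + phase)

    return make


@pytest.fixture
def clean_delta_recording():
    """Noise-free single-channel delta chain with ground truth."""
    from clasdelta import SynthConfig, make_delta_eeg

    cfg = SynthConfig(
        n_channels=1,
        frontal_gradient=(1.0,),
        noise_rms_uv=0.0,
        delta_amp_cv=0.2,
        duration_s=120.0,
        seed=11,
    )
    return make_delta_eeg(cfg)
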