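import numpy as np
import pytest

from nftrain.synth import CohortSpec, simulate_prepost_cohort


def tone(freq: float, fs: float = 250.0, duration: float = 10.0, a: float = 1.0) -> np.ndarray:
    t = np.arange(int(duration * fs)) / fs
    return a * np.sin(2 * np.pi * freq * t)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small waveform cohort shared by structural tests (3 subjects, 6 s)."""
    return simulate_prepost_cohort(CohortSpec(n_subjects=3, effect=0.0, seed=42, duration=6.0))
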