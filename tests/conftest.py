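import numpy as np
import pytest

from myofatigue.synthetic import (FatigueProfile, NoiseSpec,
                                  generate_labeled_windows)

#: class profiles used across classifier tests: well-separated RMS levels
NONFATIGUED = FatigueProfile(duration_s=1.0, rms_start=0.5, rms_end=0.5)
FATIGUED = FatigueProfile(duration_s=1.0, rms_start=2.0, rms_end=2.0)


@pytest.fixture(scope="session")
def separable_windows():
    """200 + 200 windows from well-separated classes (RMS 0.5 vs 2.0 mV,
    white noise sigma 0.1 mV)."""
    return generate_labeled_windows(
        200, 1000, (NONFATIGUED, FATIGUED),
        NoiseSpec(white_sigma=0.1), seed=2024)


@pytest.fixture(scope="session")
def small_windows():
    """60 + 60 windows for quick model unit tests."""
    return generate_labeled_windows(
        60, 500, (NONFATIGUED, FATIGUED),
        NoiseSpec(white_sigma=0.1), seed=7)
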