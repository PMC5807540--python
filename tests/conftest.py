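"""Shared fixtures: short synthetic nights sized for fast, deterministic tests."""

import numpy as np
import pytest

from somnotype.io_formats import Hypnogram, Recording
from somnotype.synthetic_data import StageProfile, SynthConfig, make_montage

FS = 128.0


@pytest.fixture(scope="session")
def short_profile() -> StageProfile:
    """Stage dynamics for 20–40-min nights: quick onset, early REM allowed."""
    from somnotype.pipeline import SHORT_NIGHT_PROFILE

    return SHORT_NIGHT_PROFILE


@pytest.fixture(scope="session")
def montage8():
    return make_montage(8)


@pytest.fixture()
def quiet_config() -> SynthConfig:
    """Low background, no artifacts: for closed-form event-recovery checks."""
    cfg = SynthConfig()
    cfg.background_rms_uv = {k: 1.0 for k in cfg.background_rms_uv}
    cfg.artifacts.rate_per_h = 0.0
    return cfg


def make_recording(data: np.ndarray, fs: float = FS) -> Recording:
    labels = [f"E{i + 1}" for i in range(data.shape[0])]
    return Recording(data=np.asarray(data, float), fs=fs, labels=labels)


def constant_hypnogram(n_epochs: int, stage: str = "N2") -> Hypnogram:
    return Hypnogram(stages=[stage] * n_epochs)
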