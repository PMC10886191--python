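from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ergorula.io_formats import CHANNELS, KinematicsRecord


def neutral_angles() -> dict[str, float]:
    """A posture scoring 1 everywhere: all angles neutral, elbows at 80 deg."""
    angles = {c: 0.0 for c in CHANNELS}
    angles["lower_arm_flexion_r"] = 80.0
    angles["lower_arm_flexion_l"] = 80.0
    return angles


@pytest.fixture
def neutral_frame() -> dict[str, float]:
    return neutral_angles()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240203)


def make_record(n_frames: int, fs: float = 60.0, fill: float = 0.0,
                participant_id: str = "P01") -> KinematicsRecord:
    data = pd.DataFrame({c: np.full(n_frames, fill) for c in CHANNELS})
    return KinematicsRecord(participant_id=participant_id, sample_rate_hz=fs, data=data)


def random_record(rng: np.random.Generator, n_frames: int, fs: float = 60.0) -> KinematicsRecord:
    data = pd.DataFrame(
        {c: rng.uniform(-180.0, 180.0, size=n_frames) for c in CHANNELS}
    )
    return KinematicsRecord(participant_id="PR", sample_rate_hz=fs, data=data)
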