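import numpy as np
import pandas as pd
import pytest

from rulatime.motion_io import ALL_CHANNELS, ANGLE_CHANNELS, FLAG_CHANNELS, MotionRecording


def make_frame(**overrides) -> dict:
    """A neutral seated working frame: all angles relaxed, well supported."""
    frame = {c: 0.0 for c in ANGLE_CHANNELS}
    frame.update({c: False for c in FLAG_CHANNELS})
    frame["lower_arm_flexion_r"] = 80.0
    frame["lower_arm_flexion_l"] = 80.0
    frame["trunk_supported_flag"] = True
    frame["legs_supported_flag"] = True
    frame.update(overrides)
    return frame


def make_recording(
    n_frames: int = 24,
    rate: float = 24.0,
    frame: dict | None = None,
    columns: dict | None = None,
    **meta,
) -> MotionRecording:
    """Constant-posture recording (or per-channel overrides via ``columns``)."""
    base = frame if frame is not None else make_frame()
    data = {"t_s": np.arange(n_frames) / rate}
    for c in ALL_CHANNELS:
        data[c] = np.full(n_frames, base[c])
    if columns:
        for c, values in columns.items():
            data[c] = np.asarray(values)
    metadata = {
        "subject_id": "S1",
        "occupation": "D",
        "pair_id": "P1",
        "dwc": 1,
        "specialization": "generalist",
    }
    metadata.update(meta)
    return MotionRecording(sampling_rate=rate, data=pd.DataFrame(data), **metadata)


@pytest.fixture
def neutral_frame():
    return make_frame()


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
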