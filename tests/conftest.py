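import numpy as np
import pytest

from emgclean import (
    ContaminationMask,
    SynthParams,
    TimeSeries,
    generate_protocol,
    mix,
    synthesize_eeg,
    synthesize_emg,
)
from emgclean.synth import EyeCondition, Muscle

FS = 1000.0


@pytest.fixture(scope="session")
def muscle_block():
    """One 15-contraction muscle block: EEG, EMG, truth mask (fs=1 kHz)."""
    timeline = generate_protocol(
        1, seed=21, fs=FS, muscles=[Muscle.FRONTALIS], eye_conditions=[EyeCondition.OPEN]
    )
    params = SynthParams(fs=FS, seed=22)
    eeg = synthesize_eeg(timeline, params)
    emg, mask = synthesize_emg(timeline, params)
    return {"timeline": timeline, "params": params, "eeg": eeg, "emg": emg, "mask": mask}


@pytest.fixture(scope="session")
def contaminated_block(muscle_block):
    """The muscle block mixed at -10 dB in-burst SNR."""
    return mix(
        muscle_block["eeg"], muscle_block["emg"], muscle_block["mask"], -10.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def white_noise(rng):
    return TimeSeries(rng.standard_normal(20000), FS)


def interval_iou(a, b) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
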