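import numpy as np
import pytest

import nirsdca as nd
from helpers import noiseless_config


@pytest.fixture(scope="session")
def clean_recording() -> nd.RawRecording:
    """Short noiseless recording with a known LF transfer (gain 10, +40°)."""
    return nd.synthesize_recording(noiseless_config())


@pytest.fixture(scope="session")
def noisy_recording() -> nd.RawRecording:
    """Realistic recording: noise, scalp contamination, drift, artifacts."""
    cfg = nd.SynthConfig(
        duration_s=720.0,
        seed=11,
        artifact_spec=nd.ArtifactSpec(count=3),
        event_times={
            "ga_induction": 2.0,
            "first_attempt": 8.0,
            "reperfusion": 10.0,
            "ga_termination": 715.0,
        },
    )
    return nd.synthesize_recording(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
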