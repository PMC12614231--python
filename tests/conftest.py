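import numpy as np
import pytest

from voiceinv.params import PhysioParams
from voiceinv.source import SourceSignal, synthesize_glottal_flow


@pytest.fixture(scope="session")
def base_params() -> PhysioParams:
    """A comfortable modal-voice configuration; sigma_eff = 30 kPa exactly,
    so the string-law F0 is (1/0.032)*sqrt(30000/1040) ~ 167.8 Hz."""
    return PhysioParams(
        vf_length=16.0,
        vf_thickness=3.5,
        body_depth=6.0,
        cover_depth=2.0,
        body_stiffness=15.0,
        cover_stiffness=23.5,
        transverse_stiffness=10.0,
        glottal_angle=3.0,
        subglottal_pressure=800.0,
    )


@pytest.fixture(scope="session")
def clean_signal(base_params) -> SourceSignal:
    """Deterministic noiseless pulse train for closed-form checks."""
    return synthesize_glottal_flow(
        base_params, jitter=0.0, shimmer=0.0, aspiration=False
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
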