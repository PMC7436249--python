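import dataclasses

import numpy as np
import pytest

from radarvitals.demod import dacm_phase, phase_to_displacement
from radarvitals.pipeline import STUDY_MOTION, PipelineConfig
from radarvitals.rbm_cancel import cancel_rbm
from radarvitals.simulate import (
    RadarConfig,
    TimeBase,
    synth_baseband,
    synth_motion,
)

FS = 100.0
L = 500
M_FULL = 2**17
RESP_BAND = (0.05, 0.6)
HEART_BAND = (0.8, 3.0)


@pytest.fixture(scope="session")
def radar_cfg() -> RadarConfig:
    return RadarConfig(carrier_freq=10e9, fs=FS)


@pytest.fixture(scope="session")
def tb500() -> TimeBase:
    return TimeBase(L, FS)


@pytest.fixture(scope="session")
def study_truth(tb500):
    """Canonical study motion: cos-phased 3 mm @ 0.4 Hz + 1 mm @ 1.3 Hz + 30 mm/s."""
    return synth_motion(STUDY_MOTION, tb500)


@pytest.fixture(scope="session")
def study_xhat(study_truth, radar_cfg):
    """Demodulated displacement of the canonical study fixture."""
    frame = synth_baseband(study_truth, radar_cfg)
    return phase_to_displacement(dacm_phase(frame), radar_cfg)


@pytest.fixture(scope="session")
def study_residual(study_xhat):
    """Order-3 ANC residual of the canonical study fixture."""
    return cancel_rbm(study_xhat, order=3).z


@pytest.fixture(scope="session")
def sine_truth(tb500):
    """Literal sine-phased variant of the study motion (x(0) = 0)."""
    params = dataclasses.replace(STUDY_MOTION, phi_r=0.0, phi_h=0.0)
    return synth_motion(params, tb500)


@pytest.fixture()
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig()
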