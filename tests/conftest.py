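import numpy as np
import pytest

from heelrise import DetectionConfig
from heelrise.synthetic_gait import StrideModelParams


@pytest.fixture(scope="session")
def cfg() -> DetectionConfig:
    return DetectionConfig()


def noise_free(**kwargs) -> StrideModelParams:
    """Stride-model parameters with every noise source switched off."""
    defaults = dict(noise_sd_pos=0.0, noise_sd_imu=0.0, noise_sd_fy=0.0,
                    noise_sd_gyro=0.0)
    defaults.update(kwargs)
    return StrideModelParams(**defaults)


@pytest.fixture(scope="session")
def quiet_stride():
    """One noise-free default stride with its ground truth (session-cached)."""
    from heelrise import generate_stride
    return generate_stride(noise_free())
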