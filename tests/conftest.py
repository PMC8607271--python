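import numpy as np
import pytest

from bbbleak import (AcquisitionParams, AIFParams, blood_to_plasma,
                     population_aif)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def aif() -> AIFParams:
    return AIFParams()


@pytest.fixture(scope="session")
def frame_times(acq) -> np.ndarray:
    return acq.frame_times_s


@pytest.fixture(scope="session")
def plasma_curve(aif, frame_times):
    """Plasma input function sampled on the default 20-frame grid."""
    return blood_to_plasma(population_aif(aif, frame_times), 0.45)
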