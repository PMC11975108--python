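import numpy as np
import pytest

from gaitloop import (HillParameters, MuscleArchitecture, generate_gait_trace)


@pytest.fixture
def soleus_arch() -> MuscleArchitecture:
    return MuscleArchitecture("soleus", lo_mouse_mm=12.0, lo_human_mm=44.0,
                              fmax_human_n=2800.0, fmax_mouse_mn=280.0)


@pytest.fixture
def edl_arch() -> MuscleArchitecture:
    return MuscleArchitecture("EDL", lo_mouse_mm=12.5, lo_human_mm=69.0,
                              fmax_human_n=350.0, fmax_mouse_mn=380.0)


@pytest.fixture
def soleus_trace():
    return generate_gait_trace("soleus")


@pytest.fixture
def edl_trace():
    return generate_gait_trace("EDL")


@pytest.fixture
def hill_params() -> HillParameters:
    return HillParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
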