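import dataclasses

import numpy as np
import pytest

from endotrace.sim import presets as preset_lib
from endotrace.sim.models import CameraModel, EventKinetics


@pytest.fixture
def endocam() -> CameraModel:
    """The default 20-fps endocytosis camera."""
    return preset_lib.camera_preset("endocytosis")


@pytest.fixture
def quiet_endocam(endocam) -> CameraModel:
    """Endocytosis camera with all noise switched off."""
    return dataclasses.replace(endocam, shot_noise=False, read_noise_sd=0.0)


@pytest.fixture
def quiet_smcam() -> CameraModel:
    cam = preset_lib.camera_preset("single_molecule")
    return dataclasses.replace(cam, shot_noise=False, read_noise_sd=0.0)


@pytest.fixture
def trapezoid() -> EventKinetics:
    """The reference trapezoid: rise 13/s to 45 molecules, 6 s plateau, fall 14/s."""
    return EventKinetics(rise_rate=13.0, peak_molecules=45.0, plateau_duration=6.0, fall_rate=14.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
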