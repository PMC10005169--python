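import numpy as np
import pytest

from msimon.camera import CameraModel
from msimon.tissue import ExtinctionTable


@pytest.fixture(scope="session")
def cam() -> CameraModel:
    return CameraModel.default()


@pytest.fixture(scope="session")
def small_cam() -> CameraModel:
    """Default optics on a small 16x32 sensor for fast frame-level tests."""
    return CameraModel.default(sensor_shape=(16, 32))


@pytest.fixture(scope="session")
def tab() -> ExtinctionTable:
    return ExtinctionTable.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
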