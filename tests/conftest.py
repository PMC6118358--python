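import numpy as np
import pytest

from sdstorm import gates
from sdstorm.localize import FitConfig
from sdstorm.simulate import (
    CameraModel,
    ClusterSpec,
    FilamentSpec,
    PhotophysicsParams,
    make_scene,
)


@pytest.fixture(scope="session")
def gate_a():
    return gates.set_a()


@pytest.fixture(scope="session")
def gate_b():
    return gates.set_b()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def desk_camera():
    """Desk-scale acquisition geometry: 64 x 64 pixels of the published
    pixel size."""
    return CameraModel(frame_shape=(64, 64))


@pytest.fixture(scope="session")
def two_target_scene(desk_camera):
    """Clusters ('clathrin') plus filaments ('tubulin') filling the field."""
    fx = desk_camera.frame_shape[1] * desk_camera.pixel_size_um
    fy = desk_camera.frame_shape[0] * desk_camera.pixel_size_um
    return make_scene(
        [
            ClusterSpec(target_id="clathrin", n=30, mean_sites=40),
            FilamentSpec(target_id="tubulin", n=6, length_um=4.0),
        ],
        field_size_um=(fx, fy),
        seed=1,
    )


@pytest.fixture(scope="session")
def blinking():
    """Sparse-blinking photophysics that keeps single emitters isolated on a
    64 x 64 field."""
    return PhotophysicsParams(p_on=0.0008, mean_on_frames=2.0,
                              photons_per_frame=800.0)


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()
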