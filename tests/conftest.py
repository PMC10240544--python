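import numpy as np
import pytest

from simscope import (
    SourceSample,
    build_depot,
    default_sim_config,
)


@pytest.fixture
def sim_depot():
    """The stock hardware-free depot (XYZ stage, camera, wheel, laser, executor)."""
    return build_depot(default_sim_config(seed=3))


@pytest.fixture
def textured_sample():
    """A 2-channel random-texture source sample (non-constant everywhere)."""
    rng = np.random.default_rng(11)
    data = rng.integers(0, 4000, size=(2, 300, 320)).astype(np.uint16)
    return SourceSample(data, pixel_size_um=1.0, focus_z_um=0.0)


def attach_sample(depot, sample):
    """Point the depot's simulated camera at a specific source sample."""
    cam = depot.device_for("camera:camera")
    cam.sample = sample
    return cam
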