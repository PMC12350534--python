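import numpy as np
import pytest
from dataclasses import replace

from depthreg import simulator as sim


@pytest.fixture(scope="session")
def intr():
    return sim.default_intrinsics()


@pytest.fixture(scope="session")
def board():
    return sim.default_board()


@pytest.fixture(scope="session")
def scene():
    """Shared phantom at 2.5 mm spacing (coarse enough to keep tests fast)."""
    return sim.generate_phantom_head(seed=0, point_spacing_mm=2.5)


@pytest.fixture(scope="session")
def noiseless_preset():
    return replace(
        sim.get_preset("d405"), axial_sigma_mm=0.0, lateral_sigma_mm=0.0, dropout_rate=0.0
    )


@pytest.fixture(scope="session")
def face_capture(scene, noiseless_preset):
    """Zero-noise face capture: (camera pose, camera-frame face cloud)."""
    pose = sim.face_viewpoints(1, seed=3)[0]
    cloud, idx = sim.simulate_depth_capture(
        scene, pose, noiseless_preset, seed=1, return_indices=True
    )
    face = cloud[scene.region_labels[idx] == "face"]
    return pose, face
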