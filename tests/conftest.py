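import numpy as np
import pytest

from phenocloud.config import default_camera
from phenocloud.scene import NoiseModel, ObjectSpec, make_object_cloud


@pytest.fixture
def camera():
    return default_camera()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_cuboid():
    """Noise-free cuboid 100 x 80 x 150 without bed points."""
    spec = ObjectSpec("cuboid", (100.0, 80.0, 150.0))
    return make_object_cloud(
        spec, NoiseModel(density_pts_per_mm2=1.0), seed=7, bed_margin_mm=0.0
    )


@pytest.fixture
def clean_cuboid_with_bed():
    spec = ObjectSpec("cuboid", (100.0, 80.0, 150.0))
    return make_object_cloud(
        spec, NoiseModel(density_pts_per_mm2=1.0), seed=7, bed_margin_mm=10.0
    )
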