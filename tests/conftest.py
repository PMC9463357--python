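import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tractfinder.deformation import RadialGeometry
from tractfinder.pipeline import run_synthetic_pipeline
from tractfinder.synthetic import PhantomSpec, make_phantom_masks, make_scene


@pytest.fixture(scope="session")
def sphere_phantom():
    """Concentric spheres: brain radius 100 mm, tumour radius 20 mm, centred."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        voxel_size=4.0,
        brain_semiaxes=(100.0, 100.0, 100.0),
        tumour_centre=(0.0, 0.0, 0.0),
        tumour_radius=20.0,
    )
    brain, tumour = make_phantom_masks(spec)
    geom = RadialGeometry(brain, tumour)
    geom.compute_tables()
    return spec, brain, tumour, geom


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Default phantom: off-centre 10 mm sphere tumour in an ellipsoid brain."""
    spec = PhantomSpec()
    brain, tumour = make_phantom_masks(spec)
    geom = RadialGeometry(brain, tumour)
    geom.compute_tables()
    return spec, brain, tumour, geom


@pytest.fixture(scope="session")
def scene():
    return make_scene(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(scene):
    return run_synthetic_pipeline(scene)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
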