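import warnings

import numpy as np
import pytest

from helixswitch.geometry import fit_helix_axis
from helixswitch.model_io import select
from helixswitch.synthetic import HelixSpec, build_ideal_helix, _scene_core


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """The synthetic scenes legitimately trigger 'incomplete ring' warnings
    (the scaffold builds side chains only where the probes need them)."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*misses ring atoms.*")
        yield


@pytest.fixture(scope="session")
def ideal_helix():
    return build_ideal_helix(HelixSpec())


@pytest.fixture(scope="session")
def ideal_helix_axis(ideal_helix):
    return fit_helix_axis(select(ideal_helix, "name CA").coords)


@pytest.fixture(scope="session")
def scene_core():
    return _scene_core()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    from helixswitch.geometry import RigidTransform

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-30.0, 30.0, 3)
    return RigidTransform(R, t)
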