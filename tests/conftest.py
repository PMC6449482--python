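import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_spec():
    from mcgate.synthetic import ToyChannelSpec
    return ToyChannelSpec()


@pytest.fixture(scope="session")
def toy_open(toy_spec):
    from mcgate.synthetic import generate_toy_channel
    return generate_toy_channel(toy_spec, "open")


@pytest.fixture(scope="session")
def toy_closed(toy_spec):
    from mcgate.synthetic import generate_toy_channel
    return generate_toy_channel(toy_spec, "closed")


@pytest.fixture()
def dipeptide():
    """Small two-segment system with charged residues for energy tests."""
    from mcgate.system import SegmentSpec, build_system
    sys_ = build_system([
        SegmentSpec("A", (("ARG", 1), ("LEU", 2)), group="alpha1"),
        SegmentSpec("B", (("ASP", 1), ("SER", 2)), group="beta_subunit"),
    ])
    sys_.root_positions[1] = [7.0, 1.0, 0.5]
    sys_._canon_dirty = [True, True]
    sys_.rebuild()
    return sys_


@pytest.fixture()
def helix10():
    """Ideal 10-residue poly-alanine alpha helix."""
    from mcgate.synthetic import HELIX_PHI, HELIX_PSI, _set_backbone
    from mcgate.system import SegmentSpec, build_system
    sys_ = build_system(
        [SegmentSpec("H", tuple(("ALA", i + 1) for i in range(10)))])
    _set_backbone(sys_, "H", HELIX_PHI, HELIX_PSI)
    sys_.rebuild(force=True)
    return sys_


def rigid_motion(coords, seed=0, angle=None):
    """Apply a random proper rotation + translation to coordinates."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    if angle is None:
        rot = Rotation.random(rng=rng).as_matrix()
    else:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
    t = rng.normal(scale=5.0, size=3)
    return coords @ rot.T + t
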