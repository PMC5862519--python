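import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from micropocket import (
    FixedField,
    GeometryParams,
    Simulation,
    VesselNetwork,
    build_domain,
    create_initial_vessel,
)


class ConstantField:
    """Uniform VEGF field for isolating growth rules from transport."""

    def __init__(self, c: float):
        self.c = float(c)

    def concentration(self, points):
        return np.full(len(np.atleast_2d(points)), self.c)

    def sample(self, points):
        p = np.atleast_2d(points)
        return np.full(len(p), self.c), np.zeros((len(p), 3))


@pytest.fixture
def constant_field():
    return ConstantField


@pytest.fixture
def planar2d():
    return build_domain(GeometryParams(kind="planar_2d"))


@pytest.fixture
def planar3d():
    return build_domain(GeometryParams(kind="planar_3d"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tip_network(points, persist=None):
    """Open polyline whose last node is a migrating tip."""
    net = VesselNetwork()
    ids = [net.add_node(p) for p in points]
    for a, b in zip(ids[:-1], ids[1:]):
        net.add_segment(a, b)
    tip = ids[-1]
    net._migrating[tip] = True
    d = np.asarray(points[-1], float) - np.asarray(points[-2], float)
    net._persist[tip] = (persist if persist is not None else d / np.linalg.norm(d))
    return net, tip
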