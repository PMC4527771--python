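"""Shared fixtures: deterministic rngs and hand-built genealogies."""

import numpy as np
import pytest

from imcoal.genealogy import Genealogy
from imcoal.im_parameters import IMParameters


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def im_params():
    """A generic in-support parameter point with migration and divergence."""
    return IMParameters(theta1=2.0, theta2=2.0, thetaA=2.0, m1=0.5, m2=0.5, t_split=1.0)


def make_two_leaf(tau: float, pops=(1, 1)) -> Genealogy:
    """Two leaves coalescing at time tau."""
    time = np.array([0.0, 0.0, tau])
    parent = np.array([2, 2, -1], dtype=np.int64)
    children = np.array([[-1, -1], [-1, -1], [0, 1]], dtype=np.int64)
    return Genealogy(time, parent, children, np.array(pops, dtype=np.int64), [])


def make_three_leaf(t1: float, t2: float, pops=(1, 1, 1)) -> Genealogy:
    """Caterpillar ((0,1),2): leaves 0,1 join at t1, with 2 at t2 > t1."""
    time = np.array([0.0, 0.0, 0.0, t1, t2])
    parent = np.array([3, 3, 4, 4, -1], dtype=np.int64)
    children = np.array(
        [[-1, -1], [-1, -1], [-1, -1], [0, 1], [3, 2]], dtype=np.int64
    )
    return Genealogy(time, parent, children, np.array(pops, dtype=np.int64), [])
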