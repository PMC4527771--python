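"""The six scaled parameters of the two-population isolation-with-migration model.

The model follows two populations of scaled sizes ``theta1`` and ``theta2``
(θ = 4Nu) that split from an ancestral population of size ``thetaA`` at scaled
time ``t_split``, exchanging migrants at scaled rates ``m1`` and ``m2``
(m/u, per lineage, backward in time).  All quantities are scaled by the
neutral mutation rate u, so times are measured in expected mutations per
site.  Priors are independent uniforms on [0, bound] — the standard setup
for this model family, where the only prior information supplied is the
upper bound of each parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "IMParameters",
    "PriorSpec",
    "log_prior",
    "sample_prior",
    "propose_scalar_update",
]

#: Canonical update order for scalar parameter moves.
PARAM_NAMES = ("theta1", "theta2", "thetaA", "m1", "m2", "t_split")


@dataclass(frozen=True)
class IMParameters:
    """One point in the six-dimensional IM parameter space.

    theta1, theta2, thetaA
        Scaled population mutation parameters (4Nu) of population 1,
        population 2 and the ancestral population.
    m1, m2
        Scaled migration rates (m/u).  ``m1`` is the rate, per lineage and
        backward in time, at which a lineage currently in population 1 moves
        to population 2; ``m2`` is the converse.
    t_split
        Scaled divergence time (t/u): looking backward, the two populations
        merge into the ancestral one at this time.
    """

    theta1: float
    theta2: float
    thetaA: float
    m1: float
    m2: float
    t_split: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "IMParameters":
        values = [float(v) for v in values]
        if len(values) != 6:
            raise ValueError("expected 6 parameter values")
        return cls(*values)

    def with_value(self, name: str, value: float) -> "IMParameters":
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        return replace(self, **{name: float(value)})


@dataclass(frozen=True)
class PriorSpec:
    """Upper bounds of the independent Uniform(0, bound) priors."""

    theta1: float = 10.0
    theta2: float = 10.0
    thetaA: float = 10.0
    m1: float = 10.0
    m2: float = 10.0
    t_split: float = 10.0

    def __post_init__(self):
        for name in PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"prior bound for {name} must be positive")

    def bound(self, name: str) -> float:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        return float(getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)


def log_prior(params: IMParameters, priors: PriorSpec) -> float:
    """Joint log prior density; ``-inf`` outside the box [0, bound]^6."""
    lp = 0.0
    for name in PARAM_NAMES:
        x = getattr(params, name)
        b = priors.bound(name)
        if x < 0.0 or x > b:
            return -math.inf
        lp -= math.log(b)
    return lp


def sample_prior(priors: PriorSpec, rng: np.random.Generator) -> IMParameters:
    """Draw one parameter point from the prior."""
    return IMParameters.from_array(rng.uniform(0.0, priors.as_array()))


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold x back into [lo, hi] by reflection at both boundaries."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def propose_scalar_update(
    params: IMParameters,
    which: str,
    window: float,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> tuple[IMParameters, float]:
    """Sliding-window move on one parameter, reflected at 0 and the bound.

    Returns the proposed parameters and the log Hastings ratio, which is 0
    because reflection keeps the proposal symmetric.
    """
    if which not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {which!r}")
    if window <= 0:
        raise ValueError("window must be positive")
    old = getattr(params, which)
    bound = priors.bound(which)
    new = _reflect(old + rng.uniform(-window / 2.0, window / 2.0), 0.0, bound)
    return params.with_value(which, new), 0.0
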