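"""Branch creation rules and type II branch dynamics.

Two branch classes are modelled.  Type I branches are long (> 10 um),
stable collaterals that grow by the same stochastic kernel as the main
axon; they appear either at random (with per-time-unit probability ``p_b``)
or upon mechanical contact (after two obstacles within one time unit).
Type II branches are short (2-10 um), highly dynamic protrusions that
re-orient every time unit and persist only if they stabilize by touching
another branch tip or branch point; otherwise they are lost at the end of
the simulation.

Branch appearance is additionally gated by a local density rule: a new
branch is accepted when the distance to the nearest existing branch point
is at least a Poisson(lambda_b) random number, i.e. with probability equal
to the Poisson CDF evaluated at that distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "OmegaLaw",
    "BranchingParams",
    "density_gate",
    "sample_type2_length",
    "initial_branch_direction",
    "choose_type1_random_site",
]


@dataclass(frozen=True)
class OmegaLaw:
    """Initial-angle law for newborn branches.

    ``kind='uniform_sphere'`` draws directions uniformly on the unit sphere;
    ``kind='uniform_solid_angle'`` draws uniformly within ``half_angle``
    radians of the parent direction.
    """

    kind: str = "uniform_sphere"
    half_angle: float = math.pi / 4

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_sphere", "uniform_solid_angle"):
            raise ValueError(f"unknown omega law {self.kind!r}")


@dataclass(frozen=True)
class BranchingParams:
    """Branch-formation parameters for one axon.

    Parameters
    ----------
    p_b
        Probability per time unit of a random type I branching event, in
        [0, 1].  May be a callable ``p_b(position) -> float`` for presets
        whose branching propensity varies in space.
    mode
        ``'random'`` (uniform probability ``p_b`` per time unit) or
        ``'on_contact'`` (branch after two mechanical obstacles in one time
        unit).
    omega
        Initial-angle law for newborn branches.
    lambda_b
        Poisson parameter (um) of the branch-density gate.
    b_l_type1 / b_l_type2
        Maximum branch order reachable by type I / type II branches.  With
        the defaults (1 and 2) only the main axon spawns type I branches and
        type I branches may carry type II protrusions.
    type2_enabled
        Whether short dynamic type II branches are simulated at all.
    type2_mix_low
        Fraction of type II lengths drawn from the short [2, 5] um component
        (the remainder comes from (5, 10] um).
    max_branch_length
        Optional (mean, sd) of a Normal law for the maximum length of type I
        branches; negative draws are truncated at 0 and a branch stops once
        its cumulative length reaches its drawn maximum.
    """

    p_b: float | Callable[[Sequence[float]], float] = 0.0
    mode: str = "random"
    omega: OmegaLaw = field(default_factory=OmegaLaw)
    lambda_b: float = 0.0
    b_l_type1: int = 1
    b_l_type2: int = 2
    type2_enabled: bool = False
    type2_mix_low: float = 0.80
    max_branch_length: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.p_b, (int, float)) and not 0.0 <= self.p_b <= 1.0:
            raise ValueError("p_b must be in [0, 1]")
        if self.lambda_b < 0:
            raise ValueError("lambda_b must be >= 0")
        if self.b_l_type1 < 0 or self.b_l_type2 < 0:
            raise ValueError("branch order limits must be >= 0")
        if self.mode not in ("random", "on_contact"):
            raise ValueError(f"unknown branching mode {self.mode!r}")

    def p_b_at(self, position: Sequence[float]) -> float:
        return self.p_b(position) if callable(self.p_b) else float(self.p_b)


def density_gate(dist_to_nearest_branchpoint: float, lambda_b: float,
                 rng: np.random.Generator) -> bool:
    """Accept a new branch with probability CDF_Poisson(floor(dist); lambda_b).

    This is exactly the probability that the distance to the nearest branch
    point is at least a Poisson(lambda_b) random number.  ``lambda_b = 0``
    always accepts; an infinite distance (no previous branch point) always
    accepts.
    """
    if dist_to_nearest_branchpoint < 0:
        raise ValueError("distance must be >= 0")
    if lambda_b == 0 or math.isinf(dist_to_nearest_branchpoint):
        return True
    p_accept = stats.poisson.cdf(math.floor(dist_to_nearest_branchpoint), lambda_b)
    return rng.random() <= p_accept


def choose_type1_random_site(n_steps_this_tj: int, rng: np.random.Generator) -> int:
    """Uniformly choose which of this time unit's steps carries the branch point."""
    if n_steps_this_tj < 1:
        raise ValueError("need at least one step to place a branch point")
    return int(rng.integers(n_steps_this_tj))


def sample_type2_length(rng: np.random.Generator, mix_low: float = 0.80) -> float:
    """Draw a type II branch length (um) from the two-component uniform mixture.

    With probability ``mix_low`` the length is Uniform[2, 5], otherwise
    Uniform(5, 10]; support is always [2, 10] um.
    """
    if rng.random() < mix_low:
        return float(rng.uniform(2.0, 5.0))
    return float(rng.uniform(5.0, 10.0))


def _uniform_sphere_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _uniform_cap_direction(axis: np.ndarray, half_angle: float,
                           rng: np.random.Generator) -> np.ndarray:
    # uniform on the spherical cap of given half-angle around `axis`
    cos_min = math.cos(half_angle)
    cos_t = rng.uniform(cos_min, 1.0)
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    local = np.array([sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t])
    # rotate local +z onto `axis`
    axis = axis / np.linalg.norm(axis)
    if abs(axis[2]) > 0.999999:
        return local * math.copysign(1.0, axis[2])
    ref = np.array([0.0, 0.0, 1.0])
    v = np.cross(ref, axis)
    c = float(np.dot(ref, axis))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return rot @ local


def initial_branch_direction(
    omega: OmegaLaw,
    parent_direction: Sequence[float],
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw a newborn branch's initial (azimuth, elevation) from ``omega``."""
    if omega.kind == "uniform_sphere":
        direction = _uniform_sphere_direction(rng)
    else:
        direction = _uniform_cap_direction(np.asarray(parent_direction, dtype=float),
                                           omega.half_angle, rng)
    azimuth = math.atan2(direction[1], direction[0])
    elevation = math.atan2(direction[2], math.hypot(direction[0], direction[1]))
    return azimuth, elevation
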