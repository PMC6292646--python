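"""Single-axon stochastic growth kernel.

An axonal path is a chain of fixed-length 3D steps whose spherical angles
(azimuth ``theta`` in the xy plane, elevation ``phi`` toward z) follow a
Gaussian Markov chain in a tangent-transformed variable.  For a raw angle
``v`` and the local direction ``psi`` of an external attractive field, the
working variable is ``t = tan((v - psi)/2)``, which maps the circle onto the
real line so the one-step conditional law is an ordinary Normal:

    t_i | t_{i-1}  ~  N( alpha/(alpha+beta) * t_{i-1},  1/(2*(alpha+beta)) )

``alpha`` weights directional memory (rigidity) and ``beta`` the attraction
toward the field.  The chain is a stationary AR(1) process with coefficient
``gamma = alpha/(alpha+beta)`` and innovation variance
``sigma0^2 = 1/(2*(alpha+beta))``, which gives closed forms for its
stationary variance and for rescaling the model to a coarser step size.
Azimuth and elevation evolve as two independent copies of this chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "TANGENT_SENTINEL",
    "GrowthParams",
    "AttractiveField",
    "UniformField",
    "PointTargetField",
    "PiecewisePlanarField",
    "AngleState",
    "StationaryStats",
    "wrap_angle",
    "to_tangent",
    "from_tangent",
    "conditional_moments",
    "sample_next_angles",
    "advance_tip",
    "simulate_theta_chain",
    "stationary_statistics",
    "renormalize_parameters",
]

#: Sentinel returned by :func:`to_tangent` at the measure-zero singularity
#: where the wrapped angle equals +/- pi (tan(+/-pi/2) is unbounded).
TANGENT_SENTINEL = 1e8


def wrap_angle(angle: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    wrapped = math.remainder(angle, 2.0 * math.pi)
    if wrapped <= -math.pi:  # remainder may return exactly -pi
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the per-step growth kernel for one axon (or branch).

    Parameters
    ----------
    alpha
        Rigidity weight (directional persistence), dimensionless, >= 0.
    beta
        Attraction weight toward the external field, dimensionless, >= 0.
        ``alpha + beta`` must be positive.
    delta_rho
        Step length in micrometres, > 0.
    n_max
        Maximum number of net steps per time unit (sets the top speed
        ``v_max = n_max * delta_rho`` per time unit).
    n_r
        Number of steps retracted upon hitting a mechanical obstacle.
    alpha_elev, beta_elev
        Optional separate weights for the elevation chain.  By default the
        azimuth and elevation chains share ``(alpha, beta)``.
    """

    alpha: float
    beta: float
    delta_rho: float = 1.0
    n_max: int = 6
    n_r: int = 2
    alpha_elev: float | None = None
    beta_elev: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ValueError("alpha + beta must be positive")
        if self.delta_rho <= 0:
            raise ValueError("delta_rho must be positive")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.n_r < 0 or self.n_r > self.n_max:
            raise ValueError("n_r must be in [0, n_max]")

    @property
    def gamma(self) -> float:
        """AR(1) coefficient alpha/(alpha+beta), in [0, 1]."""
        return self.alpha / (self.alpha + self.beta)

    @property
    def sigma0_sq(self) -> float:
        """Innovation variance 1/(2*(alpha+beta))."""
        return 1.0 / (2.0 * (self.alpha + self.beta))

    @property
    def v_max(self) -> float:
        """Maximum growth speed per time unit (um)."""
        return self.n_max * self.delta_rho

    def elevation_params(self) -> tuple[float, float]:
        a = self.alpha if self.alpha_elev is None else self.alpha_elev
        b = self.beta if self.beta_elev is None else self.beta_elev
        return a, b


class AttractiveField(Protocol):
    """External attractive field: maps a 3D position to attraction angles."""

    def azimuth_at(self, position: Sequence[float]) -> float:
        """Azimuth (rad) of the attraction direction at ``position``."""
        ...

    def elevation_at(self, position: Sequence[float]) -> float:
        """Elevation (rad) of the attraction direction at ``position``."""
        ...


@dataclass(frozen=True)
class UniformField:
    """Spatially uniform field with fixed azimuth/elevation (default +x)."""

    azimuth: float = 0.0
    elevation: float = 0.0

    def azimuth_at(self, position: Sequence[float]) -> float:
        return self.azimuth

    def elevation_at(self, position: Sequence[float]) -> float:
        return self.elevation


@dataclass(frozen=True)
class PointTargetField:
    """Field pointing from every position toward a fixed 3D target."""

    target: tuple[float, float, float]

    def _direction(self, position: Sequence[float]) -> tuple[float, float, float]:
        dx = self.target[0] - position[0]
        dy = self.target[1] - position[1]
        dz = self.target[2] - position[2]
        if dx == dy == dz == 0.0:
            return (1.0, 0.0, 0.0)
        return (dx, dy, dz)

    def azimuth_at(self, position: Sequence[float]) -> float:
        dx, dy, _ = self._direction(position)
        return math.atan2(dy, dx)

    def elevation_at(self, position: Sequence[float]) -> float:
        dx, dy, dz = self._direction(position)
        return math.atan2(dz, math.hypot(dx, dy))


@dataclass(frozen=True)
class PiecewisePlanarField:
    """Axial field that bends sideways past a threshold plane.

    Points with ``x <= x_split`` are attracted along +x; beyond the split the
    azimuth becomes ``+bend`` for y > 0 and ``-bend`` for y <= 0.  Used by the
    zebrafish retinal-ganglion-cell preset, where distal arbors fan out.
    """

    x_split: float = 60.0
    bend: float = 1.3

    def azimuth_at(self, position: Sequence[float]) -> float:
        if position[0] <= self.x_split:
            return 0.0
        return self.bend if position[1] > 0 else -self.bend

    def elevation_at(self, position: Sequence[float]) -> float:
        return 0.0


@dataclass(frozen=True)
class AngleState:
    """Instantaneous kinematic state of a growing tip."""

    position: tuple[float, float, float]
    azimuth: float
    elevation: float

    def direction(self) -> tuple[float, float, float]:
        ce = math.cos(self.elevation)
        return (
            ce * math.cos(self.azimuth),
            ce * math.sin(self.azimuth),
            math.sin(self.elevation),
        )


@dataclass(frozen=True)
class StationaryStats:
    """Closed-form second-order statistics of the tangent-variable chain."""

    gamma: float
    sigma0_sq: float
    var_theta: float
    var_dtheta: float
    chain_length: float  # math.inf for the stationary limit
    diverged: bool = False


def to_tangent(angle: float, field_angle: float) -> float:
    """Map a raw angle onto the real line relative to the field direction.

    Returns ``tan((angle - field_angle)/2)`` with the difference wrapped into
    (-pi, pi].  At the singular point +/-pi a signed sentinel of magnitude
    :data:`TANGENT_SENTINEL` is returned (a probability-zero event under the
    continuous model).
    """
    d = wrap_angle(angle - field_angle)
    if math.isclose(abs(d), math.pi, rel_tol=0.0, abs_tol=1e-12):
        return math.copysign(TANGENT_SENTINEL, d)
    return math.tan(0.5 * d)


def from_tangent(theta: float, field_angle: float) -> float:
    """Inverse of :func:`to_tangent`: ``field_angle + 2*atan(theta)``, wrapped."""
    return wrap_angle(field_angle + 2.0 * math.atan(theta))


def conditional_moments(theta_prev: float, params: GrowthParams) -> tuple[float, float]:
    """Mean and variance of the next tangent variable given the current one."""
    return params.gamma * theta_prev, params.sigma0_sq


def sample_next_angles(
    state: AngleState,
    params: GrowthParams,
    field: AttractiveField,
    rng: np.random.Generator,
) -> AngleState:
    """Draw the next step's (azimuth, elevation) from the conditional Normals.

    The field is evaluated at the current position; the previous raw angles
    are re-expressed in the local tangent variable before the AR(1) draw, so
    spatially varying fields are handled without any special casing.  The
    position is unchanged (see :func:`advance_tip`).
    """
    psi = field.azimuth_at(state.position)
    psi0 = field.elevation_at(state.position)

    theta_prev = to_tangent(state.azimuth, psi)
    phi_prev = to_tangent(state.elevation, psi0)

    mean_az, var_az = conditional_moments(theta_prev, params)
    a_el, b_el = params.elevation_params()
    gamma_el = a_el / (a_el + b_el)
    var_el = 1.0 / (2.0 * (a_el + b_el))

    theta = mean_az + math.sqrt(var_az) * rng.standard_normal()
    phi = gamma_el * phi_prev + math.sqrt(var_el) * rng.standard_normal()

    return AngleState(
        position=state.position,
        azimuth=from_tangent(theta, psi),
        elevation=from_tangent(phi, psi0),
    )


def advance_tip(state: AngleState, params: GrowthParams) -> tuple[float, float, float]:
    """New tip position one step of length ``delta_rho`` along the state angles."""
    x, y, z = state.position
    dx, dy, dz = state.direction()
    r = params.delta_rho
    return (x + r * dx, y + r * dy, z + r * dz)


def simulate_theta_chain(
    params: GrowthParams,
    n_steps: int,
    rng: np.random.Generator,
    theta0: float = 0.0,
) -> np.ndarray:
    """Simulate the tangent-variable AR(1) chain free of interactions.

    Returns an array of length ``n_steps`` holding theta_1..theta_n (the
    initial value ``theta0`` is not included).
    """
    gamma = params.gamma
    sigma0 = math.sqrt(params.sigma0_sq)
    innovations = rng.standard_normal(n_steps) * sigma0
    out = np.empty(n_steps)
    theta = theta0
    for i in range(n_steps):
        theta = gamma * theta + innovations[i]
        out[i] = theta
    return out


def stationary_statistics(params: GrowthParams, chain_length: float = math.inf) -> StationaryStats:
    """Closed-form variance of the tangent chain and of its increments.

    For a chain of length ``M`` started at theta_0 = 0 the variance is
    ``sigma0^2 * (1 - gamma^(2M)) / (1 - gamma^2)``; for ``M = inf`` it is the
    stationary value ``sigma0^2 / (1 - gamma^2)`` and the increment variance
    is ``2*sigma0^2*(1-gamma)/(1-gamma^2)``.  With ``beta = 0`` (gamma = 1)
    the stationary limit diverges and the result is flagged.
    """
    gamma = params.gamma
    s0 = params.sigma0_sq
    if gamma >= 1.0:
        if math.isinf(chain_length):
            return StationaryStats(gamma, s0, math.inf, math.inf, chain_length, diverged=True)
        # random walk: var after M steps is M * sigma0^2; increments are iid
        m = float(chain_length)
        return StationaryStats(gamma, s0, m * s0, s0, chain_length, diverged=False)
    denom = 1.0 - gamma * gamma
    if math.isinf(chain_length):
        var_theta = s0 / denom
    else:
        var_theta = s0 * (1.0 - gamma ** (2.0 * float(chain_length))) / denom
    var_dtheta = 2.0 * s0 * (1.0 - gamma) / denom
    return StationaryStats(gamma, s0, var_theta, var_dtheta, chain_length)


def renormalize_parameters(params: GrowthParams, m: int) -> GrowthParams:
    """Equivalent kernel parameters at a coarser step size ``m * delta_rho``.

    Subsampling the AR(1) tangent chain every ``m`` steps yields another AR(1)
    chain with coefficient ``gamma^m`` and the same stationary variance, from
    which the coarse-scale (alpha, beta) follow:

        gamma'     = gamma^m
        sigma0'^2  = var_theta_inf * (1 - gamma'^2)
        alpha'     = gamma' / (2 * sigma0'^2)
        beta'      = 1 / (2 * sigma0'^2) - alpha'

    This ignores re-evaluation of a non-uniform field between sub-steps, so it
    is exact for uniform fields and an approximation otherwise.
    """
    if m < 1 or int(m) != m:
        raise ValueError("renormalization factor m must be an integer >= 1")
    m = int(m)
    if m == 1:
        return params
    gamma = params.gamma
    if gamma >= 1.0:
        raise ValueError("renormalization requires gamma < 1 (beta > 0)")
    def _coarse(alpha: float, beta: float) -> tuple[float, float]:
        g = alpha / (alpha + beta)
        s0 = 1.0 / (2.0 * (alpha + beta))
        var_inf = s0 / (1.0 - g * g)
        g_m = g**m
        s0_m = var_inf * (1.0 - g_m * g_m)
        a_m = g_m / (2.0 * s0_m)
        return a_m, 1.0 / (2.0 * s0_m) - a_m

    alpha_m, beta_m = _coarse(params.alpha, params.beta)
    alpha_el_m: float | None = None
    beta_el_m: float | None = None
    if params.alpha_elev is not None or params.beta_elev is not None:
        a_el, b_el = params.elevation_params()
        if b_el <= 0:
            raise ValueError("renormalization requires gamma < 1 (beta > 0)")
        alpha_el_m, beta_el_m = _coarse(a_el, b_el)
    return replace(
        params,
        alpha=alpha_m,
        beta=beta_m,
        delta_rho=params.delta_rho * m,
        alpha_elev=alpha_el_m,
        beta_elev=beta_el_m,
    )
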