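"""Moment-based parameter estimation for the angular growth chain.

The tangent-variable chain is AR(1) with coefficient ``gamma`` and
innovation variance ``sigma0^2``, so its stationary variance and the
variance of its increments identify both parameters:

    var_theta  = sigma0^2 / (1 - gamma^2)
    var_dtheta = 2 * sigma0^2 * (1 - gamma) / (1 - gamma^2)

Inverting,

    gamma_hat     = 1 - var_dtheta_hat / (2 * var_theta_hat)
    sigma0_sq_hat = var_theta_hat * (1 - gamma_hat^2)
    alpha_hat     = gamma_hat / (2 * sigma0_sq_hat)
    beta_hat      = 1 / (2 * sigma0_sq_hat) - alpha_hat

The estimator assumes long, interaction-free chains.  When axons grow in a
crowded population, collisions break the Markov chain and bias per-axon
estimates; :func:`context_calibrate` corrects for this by simulating
populations over a grid of (alpha, beta), re-estimating per-axon parameters
under the same conditions, and choosing the grid point whose estimate
distributions best match those from the data (sum of rank-test p-values,
optionally smoothed by a quadratic surface).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .path_model import AttractiveField, to_tangent

__all__ = [
    "AngleSequence",
    "EstimationResult",
    "CalibrationResult",
    "resample_polyline",
    "extract_theta_sequence",
    "estimate_from_moments",
    "estimate_alpha_beta",
    "pooled_estimate",
    "compute_branch_probability",
    "estimate_lambda_b",
    "context_calibrate",
]


@dataclass(frozen=True)
class AngleSequence:
    """A field-relative tangent-variable sequence extracted from one axon."""

    theta: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta sequence contains non-finite values")

    def __len__(self) -> int:
        return len(self.theta)


@dataclass(frozen=True)
class EstimationResult:
    alpha_hat: float
    beta_hat: float
    gamma_hat: float
    sigma0_sq_hat: float
    var_theta_hat: float
    var_dtheta_hat: float
    valid: bool


@dataclass(frozen=True)
class CalibrationResult:
    alpha_star: float
    beta_star: float
    grid_alpha: np.ndarray
    grid_beta: np.ndarray
    scores: np.ndarray  # raw p-value sums, shape (len(grid_alpha), len(grid_beta))
    smoothed: np.ndarray


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a 3D polyline at uniform arc-length ``spacing``."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ValueError("need an (N, 3) array with N >= 2")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise ValueError("degenerate path of zero length")
    targets = np.arange(0.0, total + 1e-9, spacing)
    out = np.empty((len(targets), 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arc, points[:, k])
    return out


def extract_theta_sequence(
    path: np.ndarray,
    field: AttractiveField,
    delta_rho: float,
    angle: str = "azimuth",
    resample: bool = True,
    source_id: str = "",
) -> AngleSequence:
    """Tangent-variable sequence of a 3D path relative to the field.

    For each step ``i`` the raw azimuth/elevation is computed from the step
    vector and the field angle is evaluated at the step's start point, as in
    the generative model.  ``angle`` selects the azimuth or elevation chain.
    """
    pts = np.asarray(path, dtype=float)
    if len(pts) < 2:
        raise ValueError("path must contain at least 2 points")
    if resample:
        pts = resample_polyline(pts, delta_rho)
    if len(pts) < 2:
        raise ValueError("path too short after resampling")
    thetas = []
    for i in range(1, len(pts)):
        d = pts[i] - pts[i - 1]
        if angle == "azimuth":
            raw = math.atan2(d[1], d[0])
            psi = field.azimuth_at(pts[i - 1])
        elif angle == "elevation":
            raw = math.atan2(d[2], math.hypot(d[0], d[1]))
            psi = field.elevation_at(pts[i - 1])
        else:
            raise ValueError("angle must be 'azimuth' or 'elevation'")
        thetas.append(to_tangent(raw, psi))
    return AngleSequence(np.array(thetas), source_id=source_id)


def estimate_from_moments(var_theta: float, var_dtheta: float) -> EstimationResult:
    """Invert the stationary-moment equations; flags invalid regimes."""
    if var_theta <= 0 or var_dtheta <= 0:
        return EstimationResult(math.nan, math.nan, math.nan, math.nan,
                                var_theta, var_dtheta, valid=False)
    gamma = 1.0 - var_dtheta / (2.0 * var_theta)
    sigma0_sq = var_theta * (1.0 - gamma * gamma)
    if not (0.0 < gamma < 1.0) or sigma0_sq <= 0:
        return EstimationResult(math.nan, math.nan, gamma, sigma0_sq,
                                var_theta, var_dtheta, valid=False)
    alpha = gamma / (2.0 * sigma0_sq)
    beta = 1.0 / (2.0 * sigma0_sq) - alpha
    return EstimationResult(alpha, beta, gamma, sigma0_sq,
                            var_theta, var_dtheta, valid=True)


def estimate_alpha_beta(seq: AngleSequence) -> EstimationResult:
    """Estimate (alpha, beta) from one tangent-variable sequence."""
    theta = seq.theta
    if len(theta) < 10:
        raise ValueError("sequence too short for estimation (need >= 10 values)")
    var_theta = float(np.var(theta))
    var_dtheta = float(np.var(np.diff(theta)))
    return estimate_from_moments(var_theta, var_dtheta)


def pooled_estimate(sequences: Sequence[AngleSequence]) -> EstimationResult:
    """Estimate from several sequences of one axon (e.g. azimuth + elevation).

    Variances are pooled across sequences, weighting by length; increments
    are never taken across sequence boundaries.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    values = np.concatenate([s.theta for s in sequences])
    diffs = np.concatenate([np.diff(s.theta) for s in sequences])
    if len(diffs) == 0:
        raise ValueError("sequences too short to form increments")
    return estimate_from_moments(float(np.var(values)), float(np.var(diffs)))


def compute_branch_probability(
    mean_main_length: float,
    delta_rho: float,
    n_max: int,
    mean_type1_count: float,
) -> float:
    """Branching probability per time unit from population-mean morphometrics.

    The mean number of time units needed to grow the mean main-axon length is
    ``mean_main_length / (n_max * delta_rho)``; dividing the mean type I
    branch count per axon by it gives the per-time-unit probability.
    """
    if mean_main_length <= 0 or delta_rho <= 0 or n_max <= 0:
        raise ValueError("lengths and rates must be positive")
    if mean_type1_count < 0:
        raise ValueError("branch count must be >= 0")
    n_time_units = mean_main_length / (n_max * delta_rho)
    return mean_type1_count / n_time_units


def estimate_lambda_b(inter_branch_distances: Sequence[float]) -> float:
    """Empirical rate fit for the branch-spacing parameter: the mean
    inter-branch-point distance."""
    arr = np.asarray(inter_branch_distances, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one inter-branch distance")
    return float(arr.mean())


def context_calibrate(
    data_estimates: Sequence[EstimationResult],
    simulate_estimates: Callable[[float, float, int], Sequence[EstimationResult]],
    grid_alpha: Sequence[float],
    grid_beta: Sequence[float],
    replicates: int = 2,
    seed: int = 0,
    smooth: bool = True,
) -> CalibrationResult:
    """Simulation-in-the-loop calibration of (alpha, beta).

    For each grid point, ``simulate_estimates(alpha, beta, rep_seed)`` must
    run the population simulator under the study conditions and return the
    per-axon estimates.  The score at a grid point is the sum of the two
    Kruskal-Wallis p-values comparing the simulated alpha-hat and beta-hat
    distributions with the data's; the returned optimum maximizes the score
    (optionally smoothed by a least-squares quadratic surface), tie-broken
    by the smallest alpha + beta.
    """
    grid_alpha = np.asarray(list(grid_alpha), dtype=float)
    grid_beta = np.asarray(list(grid_beta), dtype=float)
    if grid_alpha.size == 0 or grid_beta.size == 0:
        raise ValueError("empty calibration grid")
    data_a = np.array([e.alpha_hat for e in data_estimates if e.valid])
    data_b = np.array([e.beta_hat for e in data_estimates if e.valid])
    if data_a.size == 0:
        raise ValueError("no valid data estimates")

    scores = np.zeros((grid_alpha.size, grid_beta.size))
    for i, a in enumerate(grid_alpha):
        for j, b in enumerate(grid_beta):
            sim_a: list[float] = []
            sim_b: list[float] = []
            for rep in range(replicates):
                rep_seed = (seed * 1_000_003 + i * 101 + j * 13 + rep) % (2**31 - 1)
                for e in simulate_estimates(float(a), float(b), rep_seed):
                    if e.valid:
                        sim_a.append(e.alpha_hat)
                        sim_b.append(e.beta_hat)
            if not sim_a:
                scores[i, j] = 0.0
                continue
            p_a = stats.kruskal(data_a, np.array(sim_a)).pvalue
            p_b = stats.kruskal(data_b, np.array(sim_b)).pvalue
            scores[i, j] = p_a + p_b

    smoothed = _quadratic_smooth(grid_alpha, grid_beta, scores) if smooth else scores
    flat = np.argwhere(smoothed == smoothed.max())
    # tie-break by smallest alpha + beta
    best = min(flat.tolist(), key=lambda ij: grid_alpha[ij[0]] + grid_beta[ij[1]])
    return CalibrationResult(
        alpha_star=float(grid_alpha[best[0]]),
        beta_star=float(grid_beta[best[1]]),
        grid_alpha=grid_alpha,
        grid_beta=grid_beta,
        scores=scores,
        smoothed=smoothed,
    )


def population_estimates(result, delta_rho: float,
                         min_len: int = 12) -> list[EstimationResult]:
    """Per-axon (alpha, beta) estimates from a finished population run.

    The main root-to-tip path of each tree is converted into azimuth and
    elevation tangent sequences against the run's own field and the pooled
    moment estimator is applied; axons whose main path is shorter than
    ``min_len`` steps are skipped.
    """
    from .metrics import main_axon_path  # deferred: metrics imports population

    out: list[EstimationResult] = []
    for tree in result.trees:
        path = main_axon_path(tree)
        if len(path) < min_len:
            continue
        seqs = [
            extract_theta_sequence(path, result.config.field, delta_rho,
                                   angle=a, resample=False)
            for a in ("azimuth", "elevation")
        ]
        out.append(pooled_estimate(seqs))
    return out


def simulator_for_config(config) -> Callable[[float, float, int], list[EstimationResult]]:
    """Adaptor for :func:`context_calibrate`: returns a closure that re-runs
    ``config`` with the growth (alpha, beta) replaced and re-estimates."""
    from dataclasses import replace as dc_replace

    from .population import run_population

    def simulate_estimates(alpha: float, beta: float, seed: int):
        growth = dc_replace(config.base.growth, alpha=alpha, beta=beta)
        cfg = dc_replace(config, base=dc_replace(config.base, growth=growth))
        result = run_population(cfg, seed=seed)
        return population_estimates(result, growth.delta_rho)

    return simulate_estimates


def _quadratic_smooth(ga: np.ndarray, gb: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Least-squares quadratic surface fitted to the score grid, evaluated on
    the grid (falls back to the raw scores for degenerate grids)."""
    aa, bb = np.meshgrid(ga, gb, indexing="ij")
    x = aa.ravel()
    y = bb.ravel()
    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    if design.shape[0] < design.shape[1]:
        return scores
    coef, *_ = np.linalg.lstsq(design, scores.ravel(), rcond=None)
    return (design @ coef).reshape(scores.shape)
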