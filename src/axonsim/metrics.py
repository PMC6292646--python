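"""Morphometrics of simulated or reconstructed axonal trees.

The quantities mirror those used to compare simulated populations with
reference reconstructions: main-axon length (3D and xy-projected), traveled
distance along the growth axis, branch counts split at the 10 um type I /
type II length threshold, branch directionality angles in the xy plane, and
axial profiles of branch-point counts and segment density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import AxonTree, SimulationResult

__all__ = [
    "TYPE_LENGTH_THRESHOLD",
    "MorphometryRecord",
    "main_axon_path",
    "path_length",
    "path_length_2d",
    "traveled_distance",
    "directionality_angle",
    "morphometry_record",
    "morphometry_summary",
    "axial_profiles",
]

#: Final branch length (um) separating short dynamic protrusions (type II)
#: from long stable collaterals (type I).
TYPE_LENGTH_THRESHOLD = 10.0


@dataclass(frozen=True)
class MorphometryRecord:
    axon_id: int
    main_length_3d: float
    main_length_2d: float
    traveled: float
    n_type1: int
    n_type2: int
    elongated: bool
    branch_angles: tuple[float, ...]
    branch_point_x: tuple[float, ...]


def _branch_path(tree: AxonTree, branch) -> np.ndarray:
    """Root-to-tip coordinates through a branch's ancestry."""
    b = branch
    chain = [b.origin_position] + b.nodes
    while b.parent_branch is not None:
        parent = tree.branches[b.parent_branch]
        idx = _node_index(parent, b.origin_position)
        parent_pts = ([parent.origin_position] + parent.nodes)[: idx + 1]
        chain = parent_pts + chain[1:]  # shared origin point kept once
        b = parent
    return np.asarray(chain, dtype=float)


def _node_index(branch, position) -> int:
    pts = [branch.origin_position] + branch.nodes
    for i, p in enumerate(pts):
        if p == position:
            return i
    raise ValueError("origin position not found on parent branch")


def main_axon_path(tree: AxonTree, axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
                   ) -> np.ndarray:
    """Root-to-tip path maximizing traveled distance along ``axis``.

    Candidate tips are the main branch and all type I branches; ties are
    broken by 3D path length.  Deterministic under node re-ordering.
    """
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    seed = np.asarray(tree.seed_point)
    best: tuple[float, float] | None = None
    best_path: np.ndarray | None = None
    for branch in tree.branches:
        path = _branch_path(tree, branch)
        proj = float((path[-1] - seed) @ ax)
        length = path_length(path)
        key = (proj, length)
        if best is None or key > best:
            best = key
            best_path = path
    assert best_path is not None
    return best_path


def path_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def path_length_2d(points: np.ndarray) -> float:
    """Arc length of the xy-projection (z suppressed)."""
    points = np.asarray(points, dtype=float)[:, :2]
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def traveled_distance(tree: AxonTree, entry: tuple[float, float, float] | None = None,
                      axis: tuple[float, float, float] = (1.0, 0.0, 0.0)) -> float:
    """Maximum over tips of (tip - entry) projected onto ``axis``."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    entry_pt = np.asarray(entry if entry is not None else tree.seed_point)
    return max(
        float((np.asarray(b.tip_position) - entry_pt) @ ax) for b in tree.branches
    )


def directionality_angle(mother_chord: np.ndarray, branch_chord: np.ndarray) -> float:
    """Angle (rad, in [0, pi]) between the xy-projections of the two chords.

    Chords are first-to-last-point vectors; returns NaN when either
    projection is degenerate (zero length).
    """
    m = np.asarray(mother_chord, dtype=float)[:2]
    b = np.asarray(branch_chord, dtype=float)[:2]
    nm, nb = np.linalg.norm(m), np.linalg.norm(b)
    if nm < 1e-12 or nb < 1e-12:
        return math.nan
    c = float(np.clip(m @ b / (nm * nb), -1.0, 1.0))
    return math.acos(c)


def _branch_chord(tree: AxonTree, branch) -> np.ndarray:
    pts = [branch.origin_position] + branch.nodes
    return np.asarray(pts[-1]) - np.asarray(pts[0])


def morphometry_record(tree: AxonTree, elongated: bool = False,
                       axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
                       ) -> MorphometryRecord:
    """Per-axon metrics; branches are classified type I/II by final length
    at the 10 um threshold."""
    main = main_axon_path(tree, axis)
    n1 = n2 = 0
    angles = []
    bp_x = []
    for branch in tree.branches[1:]:
        final_len = branch.length
        if final_len > TYPE_LENGTH_THRESHOLD:
            n1 += 1
        elif final_len > 0:
            n2 += 1
        parent = tree.branches[branch.parent_branch]
        ang = directionality_angle(_branch_chord(tree, parent), _branch_chord(tree, branch))
        if not math.isnan(ang):
            angles.append(ang)
        bp_x.append(branch.origin_position[0])
    for t2 in tree.type2:
        if t2.length > TYPE_LENGTH_THRESHOLD:
            n1 += 1
        else:
            n2 += 1
        bp_x.append(t2.origin_position[0])
    return MorphometryRecord(
        axon_id=tree.axon_id,
        main_length_3d=path_length(main),
        main_length_2d=path_length_2d(main),
        traveled=traveled_distance(tree, axis=axis),
        n_type1=n1,
        n_type2=n2,
        elongated=elongated,
        branch_angles=tuple(angles),
        branch_point_x=tuple(bp_x),
    )


def morphometry_summary(result: SimulationResult,
                        axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
                        ) -> pd.DataFrame:
    """Per-axon morphometry table for a finished simulation."""
    records = [
        morphometry_record(tree, elongated=flag, axis=axis)
        for tree, flag in zip(result.trees, result.elongated)
    ]
    return pd.DataFrame(
        {
            "axon_id": [r.axon_id for r in records],
            "elongated": [r.elongated for r in records],
            "main_length_3d": [r.main_length_3d for r in records],
            "main_length_2d": [r.main_length_2d for r in records],
            "traveled_distance": [r.traveled for r in records],
            "n_type1": [r.n_type1 for r in records],
            "n_type2": [r.n_type2 for r in records],
        }
    )


def axial_profiles(result: SimulationResult, bin_width: float = 5.0
                   ) -> pd.DataFrame:
    """Axial histograms: type I branch-point counts and segment density.

    Segments are binned by the x coordinate of their midpoint; branch points
    by their x position.  Bin counts sum to the respective totals.
    """
    xs_bp = []
    xs_seg = []
    x_max = 0.0
    for tree in result.trees:
        for branch in tree.branches[1:]:
            if branch.length > TYPE_LENGTH_THRESHOLD:
                xs_bp.append(branch.origin_position[0])
        for branch in tree.branches:
            pts = [branch.origin_position] + branch.nodes
            for i in range(len(pts) - 1):
                mid = 0.5 * (pts[i][0] + pts[i + 1][0])
                xs_seg.append(mid)
                x_max = max(x_max, pts[i + 1][0])
    edges = np.arange(0.0, x_max + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    bp_counts, _ = np.histogram(xs_bp, bins=edges)
    seg_counts, _ = np.histogram(xs_seg, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "branch_points": bp_counts,
            "segments": seg_counts,
        }
    )
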