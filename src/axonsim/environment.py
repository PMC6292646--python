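"""Growth cavities and the volume-exclusion machinery.

Axons are hard tubes of diameter ``d``: a candidate growth step is accepted
only if it stays inside the growth cavity, keeps a wall clearance of at
least ``d``, and its whole segment (previous tip -> candidate position) lies
at least ``d`` away from every other deposited axonal segment.  Deposited
segments live in a uniform spatial hash so each query touches only nearby
cells; the hash is kept exactly equivalent to a brute-force scan over all
segments.

Checking the candidate *segment* (rather than only the candidate point)
against the index guarantees that no two retained non-contiguous segments can
ever approach closer than ``d``: a point-only test admits crossing segments
whose endpoints clear ``d`` while their interiors do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Protocol, Sequence

Point = tuple[float, float, float]

__all__ = [
    "Cavity",
    "CylinderCavity",
    "TaperedTubeCavity",
    "UnboundedCavity",
    "SegmentRecord",
    "SegmentIndex",
    "point_segment_distance",
    "segment_segment_distance",
    "cavity_contains",
    "wall_clearance",
    "is_position_free",
    "is_segment_free",
]


class Cavity(Protocol):
    """A growth domain with an inside test and a wall-distance measure."""

    def contains(self, p: Sequence[float]) -> bool: ...

    def wall_clearance(self, p: Sequence[float]) -> float:
        """Distance to the nearest boundary (negative outside, +inf if none)."""
        ...


@dataclass(frozen=True)
class CylinderCavity:
    """Cylinder of given radius along +x, spanning x in (0, length)."""

    radius: float
    length: float

    def contains(self, p: Sequence[float]) -> bool:
        x, y, z = p
        return 0.0 < x < self.length and y * y + z * z < self.radius * self.radius

    def wall_clearance(self, p: Sequence[float]) -> float:
        x, y, z = p
        radial = self.radius - math.hypot(y, z)
        return min(radial, x, self.length - x)


@dataclass(frozen=True)
class TaperedTubeCavity:
    """Tube along +x whose radius varies linearly from entry to end.

    A parametric stand-in for anatomical lobes: wide at the entry, narrowing
    (or widening) toward the distal end.  Radial clearance against the slanted
    wall is corrected by the cone half-angle cosine, which is exact for a
    linear profile.
    """

    radius_entry: float
    radius_end: float
    length: float

    def radius_at(self, x: float) -> float:
        t = x / self.length
        return self.radius_entry + (self.radius_end - self.radius_entry) * t

    def contains(self, p: Sequence[float]) -> bool:
        x, y, z = p
        if not 0.0 < x < self.length:
            return False
        r = self.radius_at(x)
        return y * y + z * z < r * r

    def wall_clearance(self, p: Sequence[float]) -> float:
        x, y, z = p
        slope = (self.radius_end - self.radius_entry) / self.length
        cos_taper = 1.0 / math.sqrt(1.0 + slope * slope)
        radial = (self.radius_at(x) - math.hypot(y, z)) * cos_taper
        return min(radial, x, self.length - x)


@dataclass(frozen=True)
class UnboundedCavity:
    """All of 3-space; every position is inside with infinite clearance."""

    def contains(self, p: Sequence[float]) -> bool:
        return True

    def wall_clearance(self, p: Sequence[float]) -> float:
        return math.inf


def cavity_contains(cavity: Cavity, p: Sequence[float]) -> bool:
    """True iff ``p`` is strictly inside the cavity volume."""
    return cavity.contains(p)


def wall_clearance(cavity: Cavity, p: Sequence[float]) -> float:
    """Distance from ``p`` to the nearest cavity boundary (negative outside)."""
    return cavity.wall_clearance(p)


def point_segment_distance(p: Sequence[float], a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance from point ``p`` to segment ``[a, b]``."""
    ax, ay, az = a
    ux, uy, uz = b[0] - ax, b[1] - ay, b[2] - az
    wx, wy, wz = p[0] - ax, p[1] - ay, p[2] - az
    uu = ux * ux + uy * uy + uz * uz
    if uu <= 0.0:
        return math.sqrt(wx * wx + wy * wy + wz * wz)
    t = (wx * ux + wy * uy + wz * uz) / uu
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    dx, dy, dz = wx - t * ux, wy - t * uy, wz - t * uz
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def segment_segment_distance(
    p1: Sequence[float], q1: Sequence[float], p2: Sequence[float], q2: Sequence[float]
) -> float:
    """Minimum distance between segments ``[p1, q1]`` and ``[p2, q2]``.

    Standard clamped closest-point computation; degenerate (zero-length)
    segments reduce to point-segment or point-point distances.
    """
    d1x, d1y, d1z = q1[0] - p1[0], q1[1] - p1[1], q1[2] - p1[2]
    d2x, d2y, d2z = q2[0] - p2[0], q2[1] - p2[1], q2[2] - p2[2]
    rx, ry, rz = p1[0] - p2[0], p1[1] - p2[1], p1[2] - p2[2]
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    EPS = 1e-14
    if a <= EPS and e <= EPS:
        return math.sqrt(rx * rx + ry * ry + rz * rz)
    if a <= EPS:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= EPS:
            t = 0.0
            s = min(1.0, max(0.0, -c / a))
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            s = min(1.0, max(0.0, (b * f - c * e) / denom)) if denom > EPS else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -c / a))
            elif t > 1.0:
                t = 1.0
                s = min(1.0, max(0.0, (b - c) / a))
    cx = p1[0] + s * d1x - (p2[0] + t * d2x)
    cy = p1[1] + s * d1y - (p2[1] + t * d2y)
    cz = p1[2] + s * d1z - (p2[2] + t * d2z)
    return math.sqrt(cx * cx + cy * cy + cz * cz)


class SegmentRecord(NamedTuple):
    seg_id: int
    a: Point
    b: Point
    axon_id: int
    branch_id: int
    node_a: int
    node_b: int


class SegmentIndex:
    """Uniform spatial hash of deposited axon segments.

    ``cell_size`` must be at least ``d + delta_rho`` so that inflating a
    query segment's bounding box by ``d`` and scanning the overlapped cells
    covers every segment that could possibly come within ``d`` of it.
    Query results are identical to a brute-force scan over all segments.
    """

    def __init__(self, cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.cell_size = cell_size
        self._cells: dict[tuple[int, int, int], set[int]] = {}
        self._segments: dict[int, SegmentRecord] = {}
        self._next_id = 0

    def __len__(self) -> int:
        return len(self._segments)

    def _cell_range(self, a: Point, b: Point, pad: float) -> Iterator[tuple[int, int, int]]:
        cs = self.cell_size
        lo = [math.floor((min(a[k], b[k]) - pad) / cs) for k in range(3)]
        hi = [math.floor((max(a[k], b[k]) + pad) / cs) for k in range(3)]
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    yield (i, j, k)

    def register_segment(
        self,
        a: Sequence[float],
        b: Sequence[float],
        axon_id: int,
        branch_id: int,
        node_a: int = -1,
        node_b: int = -1,
    ) -> int:
        """Insert a segment and return its id (used later for removal)."""
        seg_id = self._next_id
        self._next_id += 1
        rec = SegmentRecord(seg_id, tuple(a), tuple(b), axon_id, branch_id, node_a, node_b)
        self._segments[seg_id] = rec
        for cell in self._cell_range(rec.a, rec.b, 0.0):
            self._cells.setdefault(cell, set()).add(seg_id)
        return seg_id

    def remove_segment(self, seg_id: int) -> None:
        """Remove a segment (retraction); unknown ids raise ``KeyError``."""
        rec = self._segments.pop(seg_id)
        for cell in self._cell_range(rec.a, rec.b, 0.0):
            bucket = self._cells.get(cell)
            if bucket is not None:
                bucket.discard(seg_id)
                if not bucket:
                    del self._cells[cell]

    def candidates_near(self, a: Point, b: Point, radius: float) -> Iterator[SegmentRecord]:
        """All indexed segments whose cells overlap the inflated query box."""
        seen: set[int] = set()
        for cell in self._cell_range(a, b, radius):
            for seg_id in self._cells.get(cell, ()):
                if seg_id not in seen:
                    seen.add(seg_id)
                    yield self._segments[seg_id]

    def min_distance_to_point(self, p: Sequence[float], radius: float,
                              exclude: Iterable[int] = ()) -> float:
        """Smallest distance from ``p`` to any indexed segment within reach.

        Returns +inf when no segment lies within ``radius`` of ``p``.
        """
        p = tuple(p)
        excluded = set(exclude)
        best = math.inf
        for rec in self.candidates_near(p, p, radius):
            if rec.seg_id in excluded:
                continue
            dist = point_segment_distance(p, rec.a, rec.b)
            if dist < best:
                best = dist
        return best

    def min_distance_to_segment(self, a: Sequence[float], b: Sequence[float], radius: float,
                                exclude: Iterable[int] = ()) -> float:
        """Smallest distance from segment ``[a, b]`` to any indexed segment."""
        a, b = tuple(a), tuple(b)
        excluded = set(exclude)
        best = math.inf
        for rec in self.candidates_near(a, b, radius):
            if rec.seg_id in excluded:
                continue
            dist = segment_segment_distance(a, b, rec.a, rec.b)
            if dist < best:
                best = dist
        return best

    def records(self) -> list[SegmentRecord]:
        return list(self._segments.values())


def is_position_free(
    index: SegmentIndex,
    cavity: Cavity,
    p: Sequence[float],
    d: float,
    own_tail: Iterable[int] = (),
) -> bool:
    """Point form of the exclusion test for a candidate tip position.

    True iff ``p`` is inside the cavity with wall clearance >= ``d`` and at
    least ``d`` away from every indexed segment not in ``own_tail``.
    """
    if not cavity.contains(p) or cavity.wall_clearance(p) < d:
        return False
    return index.min_distance_to_point(p, d, exclude=own_tail) >= d


def is_segment_free(
    index: SegmentIndex,
    cavity: Cavity,
    prev: Sequence[float],
    candidate: Sequence[float],
    d: float,
    own_tail: Iterable[int] = (),
) -> bool:
    """Segment form of the exclusion test used by the growth engine.

    The candidate step segment (previous tip -> candidate position) must keep
    a distance of at least ``d`` from every indexed segment except those in
    ``own_tail`` (segments sharing a node with the candidate plus the growing
    tip's recent tail).  The candidate endpoint must also lie inside the
    cavity with wall clearance >= ``d``.  Strictly stronger than
    :func:`is_position_free`.
    """
    if not cavity.contains(candidate) or cavity.wall_clearance(candidate) < d:
        return False
    return index.min_distance_to_segment(prev, candidate, d, exclude=own_tail) >= d
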