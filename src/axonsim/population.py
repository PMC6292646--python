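"""Per-time-unit growth/retraction engine and multi-axon population runs.

Time is algorithmic: within each time unit ``t_j`` every axon (in fixed
index order) advances each of its growing tips by up to ``n_max`` steps of
length ``delta_rho``.  When a candidate step hits a mechanical obstacle
(another axon's volume or the cavity wall) the tip retracts its last few
steps and re-tries with fresh random directions (CASE A); a second obstacle
within the same time unit stops the tip until the next one (CASE B).  A
tip that fails to complete ``n_max`` net steps has its trial counter
incremented by two, and stops for good once the counter exceeds
``counter_max``.  Branching happens at the end of each time unit, either at
random or upon contact, followed by the type II branch dynamics.

The blocked candidate step is counted as the first of the ``n_r`` retracted
steps: it is extended, found to collide, and withdrawn, so ``min(n_r - 1,
steps realized this time unit)`` previously deposited steps are removed in
addition.  Candidate positions are therefore never deposited in collision,
which keeps every retained pair of non-contiguous segments at least ``d``
apart at all times.

Reproducibility: axons are iterated in index order and each axon draws all
its randomness from a dedicated substream keyed by ``(seed, axon_id)``, so a
given axon's trajectory is insensitive to the behaviour of axons with higher
indices (and to population-size changes, absent interactions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .branching import (
    BranchingParams,
    OmegaLaw,
    choose_type1_random_site,
    density_gate,
    initial_branch_direction,
    sample_type2_length,
)
from .environment import Cavity, SegmentIndex, UnboundedCavity, is_segment_free
from .path_model import (
    AngleState,
    AttractiveField,
    GrowthParams,
    advance_tip,
    sample_next_angles,
)

Point = tuple[float, float, float]

__all__ = [
    "AxonSpec",
    "StoppingRule",
    "PopulationConfig",
    "Branch",
    "Type2Branch",
    "AxonTree",
    "SimulationResult",
    "grow_tip_timestep",
    "axon_active",
    "run_population",
    "classify_elongation",
    "audit_min_separation",
]


@dataclass(frozen=True)
class AxonSpec:
    """Growth and branching rules for one axon (supports mixed genotypes)."""

    growth: GrowthParams
    branching: BranchingParams = field(default_factory=BranchingParams)
    branch_growth: GrowthParams | None = None  # kernel for type I branches

    def growth_for_branch(self) -> GrowthParams:
        return self.branch_growth if self.branch_growth is not None else self.growth


@dataclass(frozen=True)
class StoppingRule:
    """Where growth succeeds and where it is capped.

    ``region_start`` is the x coordinate where the stopping region begins
    (tips reaching it stop the whole neuron, successfully).  ``x_max`` caps
    the traveled distance of any tip.  Either may be None.
    """

    region_start: float | None = None
    x_max: float | None = None

    @staticmethod
    def for_cylinder(length: float, fraction: float = 0.9,
                     x_max: float | None = None) -> "StoppingRule":
        return StoppingRule(region_start=fraction * length, x_max=x_max)

    @staticmethod
    def for_lobe(length: float, region_width: float = 20.0,
                 x_max: float | None = None) -> "StoppingRule":
        return StoppingRule(region_start=length - region_width, x_max=x_max)


@dataclass
class PopulationConfig:
    """Full description of a population growth experiment."""

    num_ax: int
    d: float
    counter_max: int
    cavity: Cavity
    field: AttractiveField
    stopping: StoppingRule
    base: AxonSpec
    overrides: dict[int, AxonSpec] = field(default_factory=dict)
    seed: int = 0
    seed_points: list[Point] | None = None
    seed_margin: float = 0.1
    max_timesteps: int = 5000

    def spec_for(self, axon_id: int) -> AxonSpec:
        return self.overrides.get(axon_id, self.base)

    def __post_init__(self) -> None:
        if self.num_ax < 1:
            raise ValueError("num_ax must be >= 1")
        if self.d < 0:
            raise ValueError("d must be >= 0")


@dataclass
class Branch:
    """A growing (main or type I) branch: ordered step nodes plus tip state."""

    branch_id: int
    btype: str  # 'main' | 'I'
    order: int
    parent_branch: int | None
    origin_position: Point
    origin_node: int  # global node id of the origin
    growth: GrowthParams
    azimuth: float
    elevation: float
    status: str = "active"  # active | stopped_success | stopped_sibling |
    #                         stopped_counter | stopped_xmax | stopped_maxlen
    counter: int = 0
    nodes: list[Point] = field(default_factory=list)
    node_ids: list[int] = field(default_factory=list)
    angles: list[tuple[float, float]] = field(default_factory=list)
    seg_ids: list[int] = field(default_factory=list)
    max_length: float | None = None
    grew_this_tj: bool = False
    case_b_this_tj: bool = False
    tj_node_count: int = 0  # nodes retained from the current time unit

    @property
    def tip_position(self) -> Point:
        return self.nodes[-1] if self.nodes else self.origin_position

    @property
    def tip_node(self) -> int:
        return self.node_ids[-1] if self.node_ids else self.origin_node

    @property
    def length(self) -> float:
        return len(self.nodes) * self.growth.delta_rho


@dataclass
class Type2Branch:
    """Short dynamic protrusion: a single chord that re-orients each t_j."""

    parent_branch: int
    origin_position: Point
    length: float
    azimuth: float
    elevation: float
    stabilized: bool = False
    uid: int = -1

    @property
    def tip_position(self) -> Point:
        ce = math.cos(self.elevation)
        return (
            self.origin_position[0] + self.length * ce * math.cos(self.azimuth),
            self.origin_position[1] + self.length * ce * math.sin(self.azimuth),
            self.origin_position[2] + self.length * math.sin(self.elevation),
        )


@dataclass
class AxonTree:
    """One neuron: seed, growing branches, dynamic type II protrusions."""

    axon_id: int
    seed_point: Point
    spec: AxonSpec
    branches: list[Branch] = field(default_factory=list)
    type2: list[Type2Branch] = field(default_factory=list)
    branch_points: list[Point] = field(default_factory=list)
    reached: bool = False  # a tip entered the stopping region (success)
    capped: bool = False  # a tip hit the X_max traveled-distance cap

    def n_nodes(self) -> int:
        return 1 + sum(len(b.nodes) for b in self.branches)

    def tips(self) -> list[tuple[Branch, Point]]:
        return [(b, b.tip_position) for b in self.branches]

    def nearest_branch_point_distance(self, p: Point) -> float:
        if not self.branch_points:
            return math.inf
        return min(
            math.dist(p, bp) for bp in self.branch_points
        )


@dataclass
class SimulationResult:
    trees: list[AxonTree]
    elongated: list[bool]
    config: PopulationConfig
    log: dict


def _traveled(p: Point, seed: Point) -> float:
    return p[0] - seed[0]


def axon_active(branch: Branch, tree: AxonTree, config: PopulationConfig) -> bool:
    """A tip keeps growing iff it has not reached the stopping region, its
    counter is within bounds, and no sibling branch of the same neuron has
    reached the region."""
    if branch.status != "active":
        return False
    if tree.reached or tree.capped:
        return False
    if branch.counter > config.counter_max:
        return False
    rule = config.stopping
    tip = branch.tip_position
    if rule.region_start is not None and tip[0] >= rule.region_start:
        return False
    if rule.x_max is not None and _traveled(tip, tree.seed_point) >= rule.x_max:
        return False
    return True


class _Engine:
    """Mutable state shared by one population run."""

    def __init__(self, config: PopulationConfig, seed: int):
        self.config = config
        self.seed = seed
        d = config.d
        delta = max(
            config.spec_for(i).growth.delta_rho for i in range(config.num_ax)
        )
        branch_delta = max(
            config.spec_for(i).growth_for_branch().delta_rho
            for i in range(config.num_ax)
        )
        self.index = SegmentIndex(cell_size=max(d + max(delta, branch_delta), 0.5))
        self.incident: dict[int, set[int]] = {}
        self._next_node = 0
        self._next_t2 = 0
        self.obstacle_events = 0
        self.rngs = [
            np.random.default_rng([seed, axon_id]) for axon_id in range(config.num_ax)
        ]

    def new_node(self) -> int:
        nid = self._next_node
        self._next_node += 1
        return nid

    # -- index bookkeeping -------------------------------------------------
    def deposit(self, branch: Branch, axon_id: int, prev_node: int,
                position: Point, angles: tuple[float, float]) -> None:
        nid = self.new_node()
        seg = self.index.register_segment(
            branch.tip_position, position, axon_id, branch.branch_id, prev_node, nid
        )
        branch.nodes.append(position)
        branch.node_ids.append(nid)
        branch.angles.append(angles)
        branch.seg_ids.append(seg)
        self.incident.setdefault(prev_node, set()).add(seg)
        self.incident.setdefault(nid, set()).add(seg)

    def retract(self, branch: Branch, n_steps: int) -> None:
        for _ in range(n_steps):
            seg = branch.seg_ids.pop()
            nid = branch.node_ids.pop()
            branch.nodes.pop()
            branch.angles.pop()
            self.index.remove_segment(seg)
            self.incident.get(nid, set()).discard(seg)
            prev = branch.tip_node
            self.incident.get(prev, set()).discard(seg)
        if branch.nodes:
            branch.azimuth, branch.elevation = branch.angles[-1]

    def exclusion_ids(self, branch: Branch) -> set[int]:
        # segments incident to the tip node (candidate shares that node) plus
        # the tip's own recent tail: the last max(n_r, 2) + 1 nodes
        tail = max(branch.growth.n_r, 2) + 1
        ids = set(self.incident.get(branch.tip_node, ()))
        ids.update(branch.seg_ids[-tail:])
        return ids


def grow_tip_timestep(
    engine: _Engine,
    tree: AxonTree,
    branch: Branch,
    rng: np.random.Generator,
    position_free: Callable[..., bool] | None = None,
) -> str:
    """Advance one tip for one time unit.  Returns 'full', 'partial_caseB'
    or 'blocked' (CASE B with no net step retained).

    ``position_free`` may be injected for testing; it receives
    ``(prev, candidate, exclude_ids)`` and replaces the exclusion test.
    """
    config = engine.config
    params = branch.growth
    n_max, n_r = params.n_max, params.n_r
    net = 0
    obstacles = 0
    case_b = False
    branch.case_b_this_tj = False

    def _free(prev: Point, cand: Point, exclude: set[int]) -> bool:
        if position_free is not None:
            return position_free(prev, cand, exclude)
        return is_segment_free(engine.index, config.cavity, prev, cand,
                               config.d, own_tail=exclude)

    while net < n_max:
        state = AngleState(branch.tip_position, branch.azimuth, branch.elevation)
        new_state = sample_next_angles(state, params, config.field, rng)
        cand = advance_tip(new_state, params)
        if _free(branch.tip_position, cand, engine.exclusion_ids(branch)):
            prev_node = branch.tip_node
            engine.deposit(branch, tree.axon_id, prev_node, cand,
                           (new_state.azimuth, new_state.elevation))
            branch.azimuth, branch.elevation = new_state.azimuth, new_state.elevation
            net += 1
            if _tip_terminal(branch, tree, config):
                break
        else:
            obstacles += 1
            engine.obstacle_events += 1
            n_retract = min(n_r - 1, net) if n_r >= 1 else 0
            if n_retract > 0:
                engine.retract(branch, n_retract)
                net -= n_retract
            if obstacles >= 2:
                case_b = True
                break

    branch.tj_node_count = net
    branch.grew_this_tj = net > 0
    branch.case_b_this_tj = case_b
    if net < n_max and branch.status == "active" and not (tree.reached or tree.capped):
        branch.counter += 2
        if branch.counter > config.counter_max:
            branch.status = "stopped_counter"
    if case_b:
        return "blocked" if net == 0 else "partial_caseB"
    return "full"


def _tip_terminal(branch: Branch, tree: AxonTree, config: PopulationConfig) -> bool:
    """Handle success / cap conditions right after a deposit; True if the tip
    must stop growing this very step."""
    tip = branch.tip_position
    rule = config.stopping
    if rule.region_start is not None and tip[0] >= rule.region_start:
        branch.status = "stopped_success"
        tree.reached = True
        for other in tree.branches:
            if other is not branch and other.status == "active":
                other.status = "stopped_sibling"
        return True
    if rule.x_max is not None and _traveled(tip, tree.seed_point) >= rule.x_max:
        # the traveled-distance cap, like the stopping region, halts the
        # whole arbor once any one tip attains it
        branch.status = "stopped_xmax"
        tree.capped = True
        for other in tree.branches:
            if other is not branch and other.status == "active":
                other.status = "stopped_sibling"
        return True
    if branch.max_length is not None and branch.length >= branch.max_length:
        branch.status = "stopped_maxlen"
        return True
    return False


def _parent_direction(branch: Branch, site: int) -> Point:
    """Unit direction of the parent segment ending at node index ``site``."""
    pts = [branch.origin_position] + branch.nodes
    a, b = pts[site], pts[site + 1]
    v = (b[0] - a[0], b[1] - a[1], b[2] - a[2])
    n = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    return (v[0] / n, v[1] / n, v[2] / n) if n > 0 else (1.0, 0.0, 0.0)


def _spawn_type1(engine: _Engine, tree: AxonTree, parent: Branch,
                 site_node_index: int, rng: np.random.Generator) -> Branch:
    """Create a type I branch at node index ``site_node_index`` of ``parent``
    (index into parent.nodes)."""
    spec = tree.spec
    growth = spec.growth_for_branch()
    origin = parent.nodes[site_node_index]
    origin_id = parent.node_ids[site_node_index]
    az, el = initial_branch_direction(
        spec.branching.omega, _parent_direction(parent, site_node_index), rng
    )
    max_len = None
    if spec.branching.max_branch_length is not None:
        mean, sd = spec.branching.max_branch_length
        max_len = max(0.0, float(rng.normal(mean, sd)))
    child = Branch(
        branch_id=len(tree.branches),
        btype="I",
        order=parent.order + 1,
        parent_branch=parent.branch_id,
        origin_position=origin,
        origin_node=origin_id,
        growth=growth,
        azimuth=az,
        elevation=el,
        max_length=max_len,
    )
    tree.branches.append(child)
    tree.branch_points.append(origin)
    return child


def _end_of_tj_branching(engine: _Engine, tree: AxonTree,
                         rng: np.random.Generator) -> None:
    config = engine.config
    branching = tree.spec.branching
    for branch in list(tree.branches):
        if branch.status != "active" or tree.reached or tree.capped:
            continue
        spawned = False
        if branch.order + 1 <= branching.b_l_type1:
            if branching.mode == "random":
                if branch.tj_node_count > 0 and rng.random() < branching.p_b_at(branch.tip_position):
                    dist = tree.nearest_branch_point_distance(branch.tip_position)
                    if density_gate(dist, branching.lambda_b, rng):
                        offset = choose_type1_random_site(branch.tj_node_count, rng)
                        site = len(branch.nodes) - branch.tj_node_count + offset
                        _spawn_type1(engine, tree, branch, site, rng)
                        spawned = True
            else:  # on_contact
                if branch.case_b_this_tj and branch.nodes:
                    dist = tree.nearest_branch_point_distance(branch.tip_position)
                    if density_gate(dist, branching.lambda_b, rng):
                        _spawn_type1(engine, tree, branch, len(branch.nodes) - 1, rng)
                        spawned = True
        if (
            not spawned
            and branching.type2_enabled
            and branch.order + 1 <= branching.b_l_type2
            and branch.nodes
        ):
            _maybe_spawn_type2(engine, tree, branch, rng)


def _maybe_spawn_type2(engine: _Engine, tree: AxonTree, branch: Branch,
                       rng: np.random.Generator) -> None:
    """Poisson-distance placement rule for short dynamic branches: draw a
    Poisson(lambda_b) distance; if it does not exceed the distance to the
    previous branch, place the new protrusion at that distance beyond it."""
    branching = tree.spec.branching
    dpb = tree.nearest_branch_point_distance(branch.tip_position)
    r = float(rng.poisson(branching.lambda_b))
    if r > dpb:
        return
    # node on this branch at arc distance ~r beyond the branch origin (or the
    # last branch point on this branch, if any)
    ref = 0
    for i, nid in enumerate(branch.node_ids):
        if branch.nodes[i] in tree.branch_points:
            ref = i
    site = min(ref + max(1, round(r / branch.growth.delta_rho)), len(branch.nodes) - 1)
    origin = branch.nodes[site]
    az, el = initial_branch_direction(OmegaLaw("uniform_sphere"), (1.0, 0.0, 0.0), rng)
    t2 = Type2Branch(
        parent_branch=branch.branch_id,
        origin_position=origin,
        length=sample_type2_length(rng, branching.type2_mix_low),
        azimuth=az,
        elevation=el,
        uid=engine._next_t2,
    )
    engine._next_t2 += 1
    tree.type2.append(t2)
    tree.branch_points.append(origin)


def _update_type2(engine: _Engine, trees: list[AxonTree]) -> None:
    """Re-orient transient type II branches and stabilize those whose tip
    touches (within d) another branch's tip or branch point."""
    config = engine.config
    contacts: list[tuple[Point, int, int]] = []  # (position, axon_id, branch_uid)
    for tree in trees:
        for b in tree.branches:
            contacts.append((b.tip_position, tree.axon_id, b.branch_id))
        for bp in tree.branch_points:
            contacts.append((bp, tree.axon_id, -1))
        for t2 in tree.type2:
            if t2.stabilized:
                contacts.append((t2.tip_position, tree.axon_id, -1))
    if contacts:
        pts = np.array([c[0] for c in contacts])
    for tree in trees:
        rng = engine.rngs[tree.axon_id]
        for t2 in tree.type2:
            if t2.stabilized:
                continue
            az, el = initial_branch_direction(OmegaLaw("uniform_sphere"),
                                              (1.0, 0.0, 0.0), rng)
            t2.azimuth, t2.elevation = az, el
            if not contacts:
                continue
            tip = np.array(t2.tip_position)
            dist = np.linalg.norm(pts - tip, axis=1)
            origin = np.array(t2.origin_position)
            own = np.linalg.norm(pts - origin, axis=1) < 1e-9
            near = (dist <= config.d) & ~own
            if bool(near.any()):
                t2.stabilized = True


def run_population(config: PopulationConfig, seed: int | None = None) -> SimulationResult:
    """Run a full population growth experiment; reproducible from the seed."""
    seed = config.seed if seed is None else seed
    engine = _Engine(config, seed)
    seeds = (
        list(config.seed_points)
        if config.seed_points is not None
        else _place_seed_points(config, np.random.default_rng([seed, 999_983]))
    )
    trees: list[AxonTree] = []
    for axon_id in range(config.num_ax):
        spec = config.spec_for(axon_id)
        sp = seeds[axon_id]
        nid = engine.new_node()
        # zero-length marker keeps other axons one diameter away from
        # unstarted seeds; it shares the seed node so the axon's own first
        # candidate is exempt
        seg = engine.index.register_segment(sp, sp, axon_id, 0, nid, nid)
        engine.incident.setdefault(nid, set()).add(seg)
        az0 = config.field.azimuth_at(sp)
        el0 = config.field.elevation_at(sp)
        main = Branch(
            branch_id=0, btype="main", order=0, parent_branch=None,
            origin_position=sp, origin_node=nid, growth=spec.growth,
            azimuth=az0, elevation=el0,
        )
        trees.append(AxonTree(axon_id=axon_id, seed_point=sp, spec=spec,
                              branches=[main]))

    t_j = 0
    while t_j < config.max_timesteps:
        t_j += 1
        any_active = False
        for tree in trees:
            rng = engine.rngs[tree.axon_id]
            for branch in list(tree.branches):
                if not axon_active(branch, tree, config):
                    continue
                any_active = True
                grow_tip_timestep(engine, tree, branch, rng)
            _end_of_tj_branching(engine, tree, rng)
        _update_type2(engine, trees)
        if not any_active:
            break

    for tree in trees:  # transient type II branches are lost at the end
        tree.type2 = [t2 for t2 in tree.type2 if t2.stabilized]

    elongated = [classify_elongation(tree, config) for tree in trees]
    log = {
        "seed": seed,
        "num_ax": config.num_ax,
        "t_j": t_j,
        "obstacle_events": engine.obstacle_events,
        "n_segments": len(engine.index),
    }
    return SimulationResult(trees=trees, elongated=elongated, config=config, log=log)


def classify_elongation(tree: AxonTree, config: PopulationConfig) -> bool:
    """Elongated iff at least one branch tip reached the stopping region."""
    region = config.stopping.region_start
    if region is None:
        return tree.reached
    return any(b.tip_position[0] >= region for b in tree.branches) or tree.reached


def _place_seed_points(config: PopulationConfig,
                       rng: np.random.Generator) -> list[Point]:
    """Dart-throwing placement of entry points on the x=0 face, pairwise at
    least one diameter apart and one diameter clear of the wall."""
    cavity = config.cavity
    if isinstance(cavity, UnboundedCavity):
        radius = max(1.0, math.sqrt(config.num_ax) * max(config.d, 0.5))
    elif hasattr(cavity, "radius"):
        radius = cavity.radius - config.d - config.seed_margin
    elif hasattr(cavity, "radius_entry"):
        radius = cavity.radius_entry - config.d - config.seed_margin
    else:
        radius = 1.0
    if radius <= 0:
        raise ValueError("cavity too small for the requested diameter")
    min_sep = config.d + 0.01
    points: list[Point] = []
    attempts = 0
    while len(points) < config.num_ax:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("could not place seed points; cavity too crowded")
        r = radius * math.sqrt(rng.random())
        phi = rng.random() * 2.0 * math.pi
        p = (0.0, r * math.cos(phi), r * math.sin(phi))
        if all(math.dist(p, q) >= min_sep for q in points):
            points.append(p)
    return points


def audit_min_separation(result: SimulationResult) -> float:
    """Smallest distance between retained non-contiguous segments of distinct
    branches (uses the spatial index; +inf when no such pair is within reach).

    The deposition-time exclusion guarantees this is never below
    ``d - 1e-6``; the audit recomputes it from the retained geometry.
    """
    config = result.config
    d = config.d
    # rebuild an index from the retained geometry so the audit does not trust
    # the engine's bookkeeping
    index = SegmentIndex(cell_size=max(d + 1.0, 0.5))
    records = []
    for tree in result.trees:
        for b in tree.branches:
            pts = [b.origin_position] + b.nodes
            ids = [b.origin_node] + b.node_ids
            for i in range(len(b.nodes)):
                index.register_segment(pts[i], pts[i + 1], tree.axon_id,
                                       b.branch_id, ids[i], ids[i + 1])
    from .environment import segment_segment_distance

    best = math.inf
    for rec in index.records():
        for other in index.candidates_near(rec.a, rec.b, d):
            if other.seg_id <= rec.seg_id:
                continue
            if (other.axon_id, other.branch_id) == (rec.axon_id, rec.branch_id):
                continue
            if {rec.node_a, rec.node_b} & {other.node_a, other.node_b}:
                continue
            dist = segment_segment_distance(rec.a, rec.b, other.a, other.b)
            if dist < best:
                best = dist
    return best
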