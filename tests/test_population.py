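import math
from dataclasses import replace

import numpy as np
import pytest

import axonsim as ax
from axonsim.branching import BranchingParams
from axonsim.environment import CylinderCavity, UnboundedCavity
from axonsim.path_model import GrowthParams, UniformField
from axonsim.population import (
    AxonSpec,
    AxonTree,
    Branch,
    PopulationConfig,
    StoppingRule,
    _Engine,
    audit_min_separation,
    axon_active,
    classify_elongation,
    grow_tip_timestep,
    run_population,
)
from conftest import free_single_axon_config


def _engine_with_single_tip(n_max=6, n_r=2, counter_max=140):
    config = PopulationConfig(
        num_ax=1,
        d=0.23,
        counter_max=counter_max,
        cavity=UnboundedCavity(),
        field=UniformField(),
        stopping=StoppingRule(),
        base=AxonSpec(growth=GrowthParams(9.0, 2.0, n_max=n_max, n_r=n_r)),
        seed_points=[(0.0, 0.0, 0.0)],
    )
    engine = _Engine(config, seed=0)
    nid = engine.new_node()
    branch = Branch(
        branch_id=0, btype="main", order=0, parent_branch=None,
        origin_position=(0.0, 0.0, 0.0), origin_node=nid,
        growth=config.base.growth, azimuth=0.0, elevation=0.0,
    )
    tree = AxonTree(axon_id=0, seed_point=(0.0, 0.0, 0.0),
                    spec=config.base, branches=[branch])
    return engine, tree, branch


def _scripted_free(blocked_attempts):
    """Freeness callback blocking the given 1-based candidate attempts."""
    calls = {"n": 0}

    def free(prev, cand, exclude):
        calls["n"] += 1
        return calls["n"] not in blocked_attempts

    return free


class TestTimestepCases:
    def test_free_space_full_growth(self):
        engine, tree, branch = _engine_with_single_tip()
        rng = np.random.default_rng(1)
        outcome = grow_tip_timestep(engine, tree, branch, rng,
                                    position_free=_scripted_free(set()))
        assert outcome == "full"
        assert len(branch.nodes) == 6
        assert branch.counter == 0

    def test_case_a_recovers_to_n_max(self):
        # first obstacle while attempting the third step, then free space:
        # the tip still completes all six net steps this time unit
        engine, tree, branch = _engine_with_single_tip()
        rng = np.random.default_rng(1)
        outcome = grow_tip_timestep(engine, tree, branch, rng,
                                    position_free=_scripted_free({3}))
        assert outcome == "full"
        assert len(branch.nodes) == 6
        assert branch.counter == 0

    def test_case_b_stops_with_retraction(self):
        # obstacles at steps 3 and 5 with n_r = 2: the blocked candidate
        # counts as the first retracted step, so three net steps remain and
        # the counter advances by two
        engine, tree, branch = _engine_with_single_tip()
        rng = np.random.default_rng(1)
        outcome = grow_tip_timestep(engine, tree, branch, rng,
                                    position_free=_scripted_free({3, 7}))
        assert outcome == "partial_caseB"
        assert len(branch.nodes) == 3
        assert branch.counter == 2
        assert branch.case_b_this_tj

    def test_fully_blocked_tip(self):
        engine, tree, branch = _engine_with_single_tip()
        rng = np.random.default_rng(1)
        outcome = grow_tip_timestep(engine, tree, branch, rng,
                                    position_free=_scripted_free({1, 2}))
        assert outcome == "blocked"
        assert len(branch.nodes) == 0
        assert branch.counter == 2

    def test_retraction_never_crosses_time_units(self):
        # grow one full time unit, then block immediately: no previously
        # realized step may be removed
        engine, tree, branch = _engine_with_single_tip()
        rng = np.random.default_rng(1)
        grow_tip_timestep(engine, tree, branch, rng, position_free=_scripted_free(set()))
        assert len(branch.nodes) == 6
        grow_tip_timestep(engine, tree, branch, rng,
                          position_free=_scripted_free({1, 2}))
        assert len(branch.nodes) == 6

    def test_counter_stops_tip(self):
        engine, tree, branch = _engine_with_single_tip(counter_max=4)
        rng = np.random.default_rng(1)
        for _ in range(3):
            grow_tip_timestep(engine, tree, branch, rng,
                              position_free=_scripted_free({1, 2}))
        assert branch.counter == 6
        assert branch.status == "stopped_counter"
        assert not axon_active(branch, tree, engine.config)


class TestStoppingRules:
    def test_single_axon_reaches_x_max(self):
        cfg = free_single_axon_config(x_max=70.0)
        res = run_population(cfg, seed=1)
        tree = res.trees[0]
        assert tree.branches[0].tip_position[0] >= 70.0
        assert tree.n_nodes() >= 1 + 70  # at least X_max / delta_rho steps
        assert tree.branches[0].status == "stopped_xmax"

    def test_stopping_region_marks_success_and_siblings(self):
        cfg = PopulationConfig(
            num_ax=1, d=0.1, counter_max=140,
            cavity=CylinderCavity(radius=13.0, length=70.0),
            field=UniformField(),
            stopping=StoppingRule.for_cylinder(70.0, fraction=0.9, x_max=70.0),
            base=AxonSpec(
                growth=GrowthParams(9.0, 2.0),
                branching=BranchingParams(p_b=1.0, lambda_b=0.0),
            ),
        )
        res = run_population(cfg, seed=2)
        tree = res.trees[0]
        assert tree.reached
        assert res.elongated == [True]
        statuses = {b.status for b in tree.branches}
        assert "stopped_success" in statuses
        # once one tip reaches the region, no other tip keeps growing
        assert "active" not in statuses

    def test_classify_elongation_uses_region(self):
        cfg = PopulationConfig(
            num_ax=1, d=0.1, counter_max=140,
            cavity=CylinderCavity(radius=13.0, length=70.0),
            field=UniformField(),
            stopping=StoppingRule.for_cylinder(70.0, fraction=0.9),
            base=AxonSpec(growth=GrowthParams(9.0, 2.0)),
            seed_points=[(0.0, 0.0, 0.0)],
        )
        engine = _Engine(cfg, seed=0)
        nid = engine.new_node()
        branch = Branch(branch_id=0, btype="main", order=0, parent_branch=None,
                        origin_position=(0.0, 0.0, 0.0), origin_node=nid,
                        growth=cfg.base.growth, azimuth=0.0, elevation=0.0)
        tree = AxonTree(axon_id=0, seed_point=(0.0, 0.0, 0.0), spec=cfg.base,
                        branches=[branch])
        branch.nodes = [(62.0, 0.0, 0.0)]
        branch.node_ids = [1]
        branch.angles = [(0.0, 0.0)]
        assert not classify_elongation(tree, cfg)
        branch.nodes = [(63.5, 0.0, 0.0)]  # past 0.9 * 70
        assert classify_elongation(tree, cfg)


class TestPopulationRuns:
    def test_same_seed_is_bit_identical(self):
        cfg = ax.crowded_cylinder(num_ax=25, d=0.25, p_b=0.3)
        r1 = run_population(cfg, seed=9)
        r2 = run_population(cfg, seed=9)
        for t1, t2 in zip(r1.trees, r2.trees):
            assert len(t1.branches) == len(t2.branches)
            for b1, b2 in zip(t1.branches, t2.branches):
                assert b1.nodes == b2.nodes
            assert [t.tip_position for t in t1.type2] == [t.tip_position for t in t2.type2]
        assert r1.elongated == r2.elongated

    def test_branch_order_limit_respected(self):
        cfg = ax.crowded_cylinder(num_ax=10, d=0.1, p_b=1.0)  # b_l_type1 = 1
        res = run_population(cfg, seed=4)
        for tree in res.trees:
            assert all(b.order <= 1 for b in tree.branches)

    def test_volume_exclusion_invariant(self):
        cfg = ax.crowded_cylinder(num_ax=30, d=0.4, p_b=0.3)
        res = run_population(cfg, seed=6)
        assert audit_min_separation(res) >= cfg.d - 1e-6

    def test_more_axons_fail_more_at_fixed_geometry(self):
        # fixed tube, growing population: the non-elongated fraction must not
        # decrease with axon number (3-seed average)
        fracs = []
        for num_ax in (40, 100):
            vals = []
            for seed in (1, 2, 3):
                cfg = replace(ax.crowded_cylinder(num_ax=100, d=0.3, p_b=0.0),
                              num_ax=num_ax)
                res = run_population(cfg, seed=seed)
                vals.append(1 - np.mean(res.elongated))
            fracs.append(np.mean(vals))
        assert fracs[1] >= fracs[0]

    def test_longer_growth_window_helps(self):
        # larger counter_max (longer allowed growth) must not hurt elongation
        fracs = []
        for counter_max in (30, 140):
            vals = []
            for seed in (1, 2, 3):
                cfg = replace(ax.crowded_cylinder(num_ax=80, d=0.3, p_b=0.0),
                              counter_max=counter_max)
                res = run_population(cfg, seed=seed)
                vals.append(1 - np.mean(res.elongated))
            fracs.append(np.mean(vals))
        assert fracs[1] <= fracs[0]

    def test_inter_branch_spacing_increases_with_lambda(self):
        # stochastic ordering of inter-branch-point distances in lambda_b
        def mean_spacing(lambda_b, seed):
            cfg = free_single_axon_config(p_b=1.0, lambda_b=lambda_b)
            res = run_population(cfg, seed=seed)
            xs = sorted(b.origin_position[0] for b in res.trees[0].branches[1:])
            if len(xs) < 2:
                return math.inf
            return float(np.mean(np.diff(xs)))

        low = np.mean([mean_spacing(1.0, s) for s in range(5)])
        high = np.mean([mean_spacing(12.0, s) for s in range(5)])
        assert high > low

    def test_type2_lifecycle(self):
        cfg = ax.gamma_neuron(num_ax=20)
        res = run_population(cfg, seed=3)
        # all surviving type II protrusions are stabilized, with lengths in
        # the observed 2-10 um range
        for tree in res.trees:
            for t2 in tree.type2:
                assert t2.stabilized
                assert 2.0 <= t2.length <= 10.0
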