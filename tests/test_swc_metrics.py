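import math
import textwrap

import numpy as np
import pytest

import axonsim as ax
from axonsim.config import load_config
from axonsim.metrics import (
    axial_profiles,
    directionality_angle,
    main_axon_path,
    morphometry_record,
    morphometry_summary,
    path_length,
    path_length_2d,
    traveled_distance,
)
from axonsim.path_model import GrowthParams
from axonsim.population import AxonSpec, AxonTree, Branch, run_population
from axonsim.swc import SwcParseError, read_swc, write_swc
from conftest import free_single_axon_config


def _synthetic_tree(tips=(50.0, 70.0)) -> AxonTree:
    """Hand-built Y-shaped tree: main trunk along +x with one collateral."""
    spec = AxonSpec(growth=GrowthParams(9.0, 2.0))
    main_nodes = [(float(x), 0.0, 0.0) for x in range(1, int(tips[1]) + 1)]
    main = Branch(branch_id=0, btype="main", order=0, parent_branch=None,
                  origin_position=(0.0, 0.0, 0.0), origin_node=0,
                  growth=spec.growth, azimuth=0.0, elevation=0.0,
                  nodes=main_nodes,
                  node_ids=list(range(1, len(main_nodes) + 1)),
                  angles=[(0.0, 0.0)] * len(main_nodes))
    origin_idx = 19  # branch point at x = 20
    n_branch = int(tips[0]) - 20
    branch_nodes = [(20.0, float(i + 1), 0.0) for i in range(n_branch)]
    # re-point the collateral along +x after the first segment so its tip x
    # stays at 50
    branch_nodes = [(20.0 + i, 1.0, 0.0) for i in range(1, n_branch + 1)]
    side = Branch(branch_id=1, btype="I", order=1, parent_branch=0,
                  origin_position=main_nodes[origin_idx], origin_node=20,
                  growth=spec.growth, azimuth=0.0, elevation=0.0,
                  nodes=branch_nodes,
                  node_ids=list(range(1000, 1000 + n_branch)),
                  angles=[(0.0, 0.0)] * n_branch)
    tree = AxonTree(axon_id=0, seed_point=(0.0, 0.0, 0.0), spec=spec,
                    branches=[main, side],
                    branch_points=[main_nodes[origin_idx]])
    return tree


class TestSwcRoundtrip:
    def test_write_read_identity(self, tmp_path):
        cfg = free_single_axon_config(p_b=1.0, lambda_b=5.0, x_max=40.0)
        res = run_population(cfg, seed=11)
        tree = res.trees[0]
        path = tmp_path / "axon.swc"
        write_swc(tree, path, diameter=0.23)
        morph = read_swc(path)
        assert len(morph.nodes) == tree.n_nodes() + len(tree.type2)
        # geometry preserved
        xyz = morph.nodes[["x", "y", "z"]].to_numpy()
        flat = [tree.branches[0].origin_position]
        for b in tree.branches:
            flat.extend(b.nodes)
        assert np.allclose(sorted(map(tuple, xyz[: len(flat)])),
                           sorted(map(tuple, flat)), atol=1e-6)
        assert morph.sidecar is not None
        assert set(morph.sidecar.branch_type) <= {"main", "type_I", "type_II"}

    def test_node_count_conservation(self, tmp_path):
        cfg = free_single_axon_config(x_max=50.0)
        res = run_population(cfg, seed=2)
        tree = res.trees[0]
        path = tmp_path / "a.swc"
        write_swc(tree, path)
        morph = read_swc(path)
        assert len(morph.nodes) == 1 + len(tree.branches[0].nodes)

    def test_tip_paths_of_y_tree(self, tmp_path):
        tree = _synthetic_tree()
        path = tmp_path / "y.swc"
        write_swc(tree, path)
        morph = read_swc(path)
        paths = morph.tip_paths()
        assert len(paths) == 2
        assert {round(p[-1][0]) for p in paths} == {50, 70}


class TestSwcParsing:
    def _write(self, tmp_path, content):
        p = tmp_path / "bad.swc"
        p.write_text(textwrap.dedent(content))
        return p

    def test_unknown_parent_names_line(self, tmp_path):
        p = self._write(tmp_path, """\
            # comment
            1 2 0 0 0 0.1 -1
            2 2 1 0 0 0.1 99
            """)
        with pytest.raises(SwcParseError, match=r"bad\.swc:3.*unknown parent"):
            read_swc(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = self._write(tmp_path, """\
            1 2 0 0 0 0.1 -1
            1 2 1 0 0 0.1 1
            """)
        with pytest.raises(SwcParseError, match="duplicate"):
            read_swc(p)

    def test_cycle_rejected(self, tmp_path):
        p = self._write(tmp_path, """\
            1 2 0 0 0 0.1 2
            2 2 1 0 0 0.1 1
            """)
        with pytest.raises(SwcParseError, match="cyclic"):
            read_swc(p)

    def test_wrong_field_count_rejected(self, tmp_path):
        p = self._write(tmp_path, "1 2 0 0 0 0.1\n")
        with pytest.raises(SwcParseError, match="expected 7 fields"):
            read_swc(p)


class TestMorphometrics:
    def test_main_path_of_unbranched_axon_is_whole_path(self):
        cfg = free_single_axon_config(x_max=30.0)
        res = run_population(cfg, seed=1)
        tree = res.trees[0]
        main = main_axon_path(tree)
        assert len(main) == tree.n_nodes()

    def test_main_path_prefers_farther_tip(self):
        tree = _synthetic_tree(tips=(50.0, 70.0))
        main = main_axon_path(tree)
        assert main[-1][0] == pytest.approx(70.0)

    def test_traveled_distance_examples(self):
        tree = _synthetic_tree()
        assert traveled_distance(tree) == pytest.approx(70.0)
        # a single explicit tip
        spec = AxonSpec(growth=GrowthParams(9.0, 2.0))
        b = Branch(branch_id=0, btype="main", order=0, parent_branch=None,
                   origin_position=(0.0, 0.0, 0.0), origin_node=0,
                   growth=spec.growth, azimuth=0.0, elevation=0.0,
                   nodes=[(70.0, 3.0, -2.0)], node_ids=[1], angles=[(0.0, 0.0)])
        t = AxonTree(axon_id=0, seed_point=(0.0, 0.0, 0.0), spec=spec, branches=[b])
        assert traveled_distance(t) == pytest.approx(70.0)

    @pytest.mark.parametrize(
        "mother,branch,expected",
        [
            ((1, 0, 0), (0, 1, 0), math.pi / 2),
            ((1, 0, 0), (2, 0, 0), 0.0),
            ((1, 0, 0), (1, 0, 5), 0.0),  # z suppressed
            ((1, 0, 0), (-1, 0, 0), math.pi),
        ],
    )
    def test_directionality_angle(self, mother, branch, expected):
        assert directionality_angle(np.array(mother), np.array(branch)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_directionality_angle_degenerate_projection(self):
        assert math.isnan(directionality_angle(np.array([0, 0, 1.0]),
                                               np.array([1.0, 0, 0])))

    def test_branch_type_split_at_ten_microns(self):
        spec = AxonSpec(growth=GrowthParams(9.0, 2.0))
        main_nodes = [(float(x), 0.0, 0.0) for x in range(1, 31)]
        main = Branch(branch_id=0, btype="main", order=0, parent_branch=None,
                      origin_position=(0.0, 0.0, 0.0), origin_node=0,
                      growth=spec.growth, azimuth=0.0, elevation=0.0,
                      nodes=main_nodes, node_ids=list(range(1, 31)),
                      angles=[(0.0, 0.0)] * 30)

        def collateral(bid, origin_idx, n):
            return Branch(branch_id=bid, btype="I", order=1, parent_branch=0,
                          origin_position=main_nodes[origin_idx], origin_node=0,
                          growth=spec.growth, azimuth=0.0, elevation=0.0,
                          nodes=[(main_nodes[origin_idx][0], float(i + 1), 0.0)
                                 for i in range(n)],
                          node_ids=list(range(100 * bid, 100 * bid + n)),
                          angles=[(0.0, 0.0)] * n)

        tree = AxonTree(axon_id=0, seed_point=(0.0, 0.0, 0.0), spec=spec,
                        branches=[main, collateral(1, 5, 4), collateral(2, 15, 25)])
        rec = morphometry_record(tree)
        assert rec.n_type2 == 1  # 4 um collateral
        assert rec.n_type1 == 1  # 25 um collateral

    def test_population_summary_invariants(self):
        cfg = ax.crowded_cylinder(num_ax=15, d=0.25, p_b=0.3)
        res = run_population(cfg, seed=3)
        tab = morphometry_summary(res)
        assert len(tab) == 15
        assert (tab.main_length_2d <= tab.main_length_3d + 1e-9).all()
        assert (tab.traveled_distance <= tab.main_length_3d + 1e-9).all()

    def test_axial_profile_conservation(self):
        cfg = ax.crowded_cylinder(num_ax=15, d=0.25, p_b=0.3)
        res = run_population(cfg, seed=3)
        prof = axial_profiles(res, bin_width=5.0)
        n_type1 = sum(
            1 for t in res.trees for b in t.branches[1:] if b.length > 10.0
        )
        n_segments = sum(len(b.nodes) for t in res.trees for b in t.branches)
        assert prof.branch_points.sum() == n_type1
        assert prof.segments.sum() == n_segments

    def test_straight_axon_density_is_one_per_bin(self):
        spec = AxonSpec(growth=GrowthParams(9.0, 2.0))
        nodes = [(float(x), 0.0, 0.0) for x in range(1, 21)]
        b = Branch(branch_id=0, btype="main", order=0, parent_branch=None,
                   origin_position=(0.0, 0.0, 0.0), origin_node=0,
                   growth=spec.growth, azimuth=0.0, elevation=0.0,
                   nodes=nodes, node_ids=list(range(1, 21)),
                   angles=[(0.0, 0.0)] * 20)
        tree = AxonTree(axon_id=0, seed_point=(0.0, 0.0, 0.0), spec=spec, branches=[b])
        from axonsim.population import SimulationResult

        cfg = free_single_axon_config()
        res = SimulationResult(trees=[tree], elongated=[True], config=cfg, log={})
        prof = axial_profiles(res, bin_width=1.0)
        occupied = prof[prof.segments > 0]
        assert (occupied.segments == 1).all()


class TestConfigLoading:
    def test_full_config_roundtrip(self, tmp_path):
        p = tmp_path / "run.toml"
        p.write_text(textwrap.dedent("""\
            [population]
            num_ax = 5
            d = 0.25
            counter_max = 100
            seed = 3

            [growth]
            alpha = 9.0
            beta = 2.0
            delta_rho = 1.0
            n_max = 6
            n_r = 2

            [branching]
            p_b = 0.2
            lambda_b = 15.0
            b_l_type1 = 1

            [cavity]
            kind = "cylinder"
            radius = 13.0
            length = 70.0

            [field]
            kind = "uniform"

            [stopping]
            fraction = 0.9
            x_max = 70.0
        """))
        cfg = load_config(p)
        assert cfg.num_ax == 5
        assert cfg.base.growth.alpha == 9.0
        assert cfg.stopping.region_start == pytest.approx(63.0)
        res = run_population(cfg)
        assert len(res.trees) == 5

    def test_preset_with_overrides(self, tmp_path):
        p = tmp_path / "run.toml"
        p.write_text(textwrap.dedent("""\
            preset = "crowded_cylinder"

            [population]
            num_ax = 10
            d = 0.1

            [branching]
            p_b = 0.5
        """))
        cfg = load_config(p)
        assert cfg.num_ax == 10
        assert cfg.d == 0.1
        assert cfg.base.branching.p_b == 0.5
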