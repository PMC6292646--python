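"""TOML configuration for population runs.

A run file either names a packaged preset (optionally overriding scalar
fields) or spells out the whole configuration:

.. code-block:: toml

    preset = "crowded_cylinder"   # optional starting point

    [population]
    num_ax = 100
    d = 0.25
    counter_max = 140
    seed = 1

    [growth]
    alpha = 9.0
    beta = 2.0
    delta_rho = 1.0
    n_max = 6
    n_r = 2

    [branching]
    p_b = 0.2
    mode = "random"
    lambda_b = 15.0
    b_l_type1 = 1

    [cavity]
    kind = "cylinder"      # cylinder | tapered_tube | unbounded
    radius = 13.0
    length = 70.0

    [field]
    kind = "uniform"
    azimuth = 0.0
    elevation = 0.0

    [stopping]
    fraction = 0.9         # or region_start / region_width
    x_max = 70.0
"""

from __future__ import annotations

import tomllib
from dataclasses import replace
from pathlib import Path
from typing import Any

from .branching import BranchingParams, OmegaLaw
from .environment import CylinderCavity, TaperedTubeCavity, UnboundedCavity
from .path_model import GrowthParams, PointTargetField, UniformField
from .population import AxonSpec, PopulationConfig, StoppingRule

__all__ = ["load_config", "config_from_dict"]


def load_config(path: str | Path) -> PopulationConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data)


def _cavity_from(d: dict[str, Any]):
    kind = d.get("kind", "cylinder")
    if kind == "cylinder":
        return CylinderCavity(radius=float(d["radius"]), length=float(d["length"]))
    if kind == "tapered_tube":
        return TaperedTubeCavity(
            radius_entry=float(d["radius_entry"]),
            radius_end=float(d["radius_end"]),
            length=float(d["length"]),
        )
    if kind == "unbounded":
        return UnboundedCavity()
    raise ValueError(f"unknown cavity kind {kind!r}")


def _field_from(d: dict[str, Any]):
    kind = d.get("kind", "uniform")
    if kind == "uniform":
        return UniformField(
            azimuth=float(d.get("azimuth", 0.0)),
            elevation=float(d.get("elevation", 0.0)),
        )
    if kind == "point_target":
        return PointTargetField(target=tuple(float(v) for v in d["target"]))
    raise ValueError(f"unknown field kind {kind!r}")


def _stopping_from(d: dict[str, Any], cavity) -> StoppingRule:
    x_max = d.get("x_max")
    if "region_start" in d:
        return StoppingRule(region_start=float(d["region_start"]),
                            x_max=None if x_max is None else float(x_max))
    if "fraction" in d:
        return StoppingRule.for_cylinder(cavity.length, float(d["fraction"]),
                                         None if x_max is None else float(x_max))
    if "region_width" in d:
        return StoppingRule.for_lobe(cavity.length, float(d["region_width"]),
                                     None if x_max is None else float(x_max))
    return StoppingRule(region_start=None,
                        x_max=None if x_max is None else float(x_max))


def config_from_dict(data: dict[str, Any]) -> PopulationConfig:
    """Build a :class:`PopulationConfig` from parsed TOML data."""
    if "preset" in data:
        from .presets import PRESETS

        base = PRESETS[data["preset"]]()
        pop = data.get("population", {})
        updates: dict[str, Any] = {}
        for key in ("num_ax", "d", "counter_max", "seed", "max_timesteps"):
            if key in pop:
                updates[key] = pop[key]
        config = replace(base, **updates)
        if "growth" in data:
            growth = replace(base.base.growth, **data["growth"])
            config = replace(config, base=replace(base.base, growth=growth))
        if "branching" in data:
            branching = replace(config.base.branching, **_branching_kwargs(data["branching"]))
            config = replace(config, base=replace(config.base, branching=branching))
        return config

    pop = data["population"]
    growth = GrowthParams(**data["growth"])
    branching = BranchingParams(**_branching_kwargs(data.get("branching", {})))
    branch_growth = (
        GrowthParams(**data["branch_growth"]) if "branch_growth" in data else None
    )
    cavity = _cavity_from(data.get("cavity", {"kind": "unbounded"}))
    field = _field_from(data.get("field", {}))
    stopping = _stopping_from(data.get("stopping", {}), cavity)
    return PopulationConfig(
        num_ax=int(pop["num_ax"]),
        d=float(pop["d"]),
        counter_max=int(pop.get("counter_max", 140)),
        cavity=cavity,
        field=field,
        stopping=stopping,
        base=AxonSpec(growth=growth, branching=branching, branch_growth=branch_growth),
        seed=int(pop.get("seed", 0)),
        max_timesteps=int(pop.get("max_timesteps", 5000)),
    )


def _branching_kwargs(d: dict[str, Any]) -> dict[str, Any]:
    out = dict(d)
    if "omega" in out:
        om = out["omega"]
        if isinstance(om, str):
            out["omega"] = OmegaLaw(om)
        else:
            out["omega"] = OmegaLaw(om.get("kind", "uniform_sphere"),
                                    float(om.get("half_angle", 0.7853981633974483)))
    if "max_branch_length" in out and out["max_branch_length"] is not None:
        out["max_branch_length"] = tuple(float(v) for v in out["max_branch_length"])
    return out
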