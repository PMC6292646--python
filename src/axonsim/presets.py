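"""Packaged experiment presets.

Each preset returns a fully specified :class:`PopulationConfig`:

* ``crowded_cylinder`` — a population of identical axons growing in a
  cylindrical tube, used to study how diameter, axon number and branching
  probability shape the fraction of axons that fail to elongate.
* ``gamma_neuron`` — Drosophila mushroom-body gamma neurons growing into a
  tapered-tube stand-in for the medial lobe, with the parameter values
  estimated from in vivo reconstructions (alpha 7.45, beta 1.67, ...).
* ``zebrafish_rgc`` / ``human_pyramidal`` — single-neuron morphology
  presets reproducing qualitatively distinct arborization styles.

When a cylinder preset is scaled down from its reference population of 400
axons, the tube radius scales as sqrt(num_ax/400) so the number of axons per
unit cross-section (the quantity driving spatial competition) is preserved.
"""

from __future__ import annotations

import math

from .branching import BranchingParams, OmegaLaw
from .environment import CylinderCavity, TaperedTubeCavity, UnboundedCavity
from .path_model import GrowthParams, PiecewisePlanarField, UniformField
from .population import AxonSpec, PopulationConfig, StoppingRule

__all__ = [
    "crowded_cylinder",
    "gamma_neuron",
    "zebrafish_rgc",
    "human_pyramidal",
    "PRESETS",
]


def crowded_cylinder(
    num_ax: int = 400,
    d: float = 0.4,
    p_b: float = 0.0,
    seed: int = 0,
) -> PopulationConfig:
    """Crowded-cylinder experiment: axons with rigidity 9 and attraction 2
    racing down a tube (radius 13 um at the reference population of 400).

    Elongation succeeds when a tip reaches 90% of the tube length (70 um).
    """
    radius = 13.0 * math.sqrt(num_ax / 400.0)
    length = 70.0
    growth = GrowthParams(alpha=9.0, beta=2.0, delta_rho=1.0, n_max=6, n_r=2)
    branching = BranchingParams(
        p_b=p_b,
        mode="random",
        omega=OmegaLaw("uniform_sphere"),
        lambda_b=15.0,
        b_l_type1=1,
        type2_enabled=False,
    )
    return PopulationConfig(
        num_ax=num_ax,
        d=d,
        counter_max=140,
        cavity=CylinderCavity(radius=radius, length=length),
        field=UniformField(),
        stopping=StoppingRule.for_cylinder(length, fraction=0.9, x_max=70.0),
        base=AxonSpec(growth=growth, branching=branching),
        seed=seed,
    )


def gamma_neuron(
    num_ax: int = 650,
    branching_mode: str = "on_contact",
    seed: int = 0,
) -> PopulationConfig:
    """Mushroom-body gamma-neuron population in a tapered medial-lobe tube.

    Morphological parameters follow the values estimated from reconstructed
    neurons (alpha 7.45, beta 1.67, step 1 um, diameter 0.23 um, branch
    spacing 6.2 um); dynamics use n_max 6, n_r 2, counter_max 140.  The lobe
    is a 70 um tube narrowing from 10 to 5 um radius — a parametric stand-in
    for the anatomical geometry — and the stopping region is the last 20 um.
    """
    length = 70.0
    growth = GrowthParams(alpha=7.45, beta=1.67, delta_rho=1.0, n_max=6, n_r=2)
    branching = BranchingParams(
        p_b=0.15,
        mode=branching_mode,
        omega=OmegaLaw("uniform_sphere"),
        lambda_b=6.2,
        b_l_type1=1,
        b_l_type2=2,
        type2_enabled=True,
    )
    return PopulationConfig(
        num_ax=num_ax,
        d=0.23,
        counter_max=140,
        cavity=TaperedTubeCavity(radius_entry=10.0, radius_end=5.0, length=length),
        field=UniformField(),
        stopping=StoppingRule.for_lobe(length, region_width=20.0, x_max=70.0),
        base=AxonSpec(growth=growth, branching=branching),
        seed=seed,
    )


def zebrafish_rgc(seed: int = 0) -> PopulationConfig:
    """Single zebrafish retinal-ganglion-cell axon with a distally fanning
    field and dense branching past the fan point."""
    growth = GrowthParams(alpha=15.0, beta=2.0, delta_rho=1.0, n_max=10, n_r=2)
    branch_growth = GrowthParams(alpha=20.0, beta=0.5, delta_rho=1.0, n_max=10, n_r=2)
    branching = BranchingParams(
        p_b=lambda p: 0.5 if p[0] < 60.0 else 0.3,
        mode="random",
        omega=OmegaLaw("uniform_sphere"),
        lambda_b=6.0,
        b_l_type1=2,
        type2_enabled=False,
    )
    return PopulationConfig(
        num_ax=1,
        d=0.5,
        counter_max=140,
        cavity=UnboundedCavity(),
        field=PiecewisePlanarField(x_split=60.0, bend=1.3),
        stopping=StoppingRule(region_start=None, x_max=80.0),
        base=AxonSpec(growth=growth, branching=branching, branch_growth=branch_growth),
        seed=seed,
        seed_points=[(0.0, 0.0, 0.0)],
    )


def human_pyramidal(seed: int = 0) -> PopulationConfig:
    """Single human neocortical pyramidal axon: strongly field-bound main
    trunk, branches confined to a pi/4 solid angle, branch maximum lengths
    drawn from Normal(100, 70) um."""
    growth = GrowthParams(alpha=10.0, beta=30.0, delta_rho=3.0, n_max=1, n_r=1)
    branch_growth = GrowthParams(alpha=100.0, beta=10.0, delta_rho=3.0, n_max=1, n_r=1)
    branching = BranchingParams(
        p_b=lambda p: 0.0 if p[0] < 60.0 else 0.3,
        mode="random",
        omega=OmegaLaw("uniform_solid_angle", half_angle=math.pi / 4),
        lambda_b=1.0,
        b_l_type1=2,
        type2_enabled=False,
        max_branch_length=(100.0, 70.0),
    )
    return PopulationConfig(
        num_ax=1,
        d=0.5,
        counter_max=140,
        cavity=UnboundedCavity(),
        field=UniformField(),
        stopping=StoppingRule(region_start=None, x_max=110.0),
        base=AxonSpec(growth=growth, branching=branching, branch_growth=branch_growth),
        seed=seed,
        seed_points=[(0.0, 0.0, 0.0)],
    )


PRESETS = {
    "crowded_cylinder": crowded_cylinder,
    "gamma_neuron": gamma_neuron,
    "zebrafish_rgc": zebrafish_rgc,
    "human_pyramidal": human_pyramidal,
}
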