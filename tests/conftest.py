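import numpy as np
import pytest

from axonsim.branching import BranchingParams
from axonsim.environment import UnboundedCavity
from axonsim.path_model import GrowthParams, UniformField
from axonsim.population import AxonSpec, PopulationConfig, StoppingRule


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def free_single_axon_config(alpha=9.0, beta=2.0, x_max=70.0, p_b=0.0, **branch_kw):
    """One axon in unbounded space: the interaction-free reference setup."""
    return PopulationConfig(
        num_ax=1,
        d=0.23,
        counter_max=140,
        cavity=UnboundedCavity(),
        field=UniformField(),
        stopping=StoppingRule(region_start=None, x_max=x_max),
        base=AxonSpec(
            growth=GrowthParams(alpha, beta),
            branching=BranchingParams(p_b=p_b, **branch_kw),
        ),
        seed_points=[(0.0, 0.0, 0.0)],
    )


def sparse_population_config(alpha=9.0, beta=2.0, num_ax=50):
    """Widely spaced axons in unbounded space: interactions enabled but rare."""
    return PopulationConfig(
        num_ax=num_ax,
        d=0.23,
        counter_max=140,
        cavity=UnboundedCavity(),
        field=UniformField(),
        stopping=StoppingRule(region_start=None, x_max=70.0),
        base=AxonSpec(growth=GrowthParams(alpha, beta), branching=BranchingParams()),
    )


def ar1_variance_se(var: float, gamma: float, n: int) -> float:
    """Monte-Carlo s.e. of the sample variance of a Gaussian AR(1) chain.

    Var(sigma^2-hat) ~ (2 var^2 / n) * sum_k rho_k^2 with
    sum_k rho_k^2 = (1 + gamma^2) / (1 - gamma^2).
    """
    return var * np.sqrt(2.0 * (1.0 + gamma**2) / (1.0 - gamma**2) / n)
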