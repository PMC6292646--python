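"""Out-competition of a non-branching axon by branching neighbours.

A single axon unable to form long branches grows among 99 branching axons.
Across independent runs its traveled distance splits into two modes — full
elongation or early arrest — and it fails more often than axons do in an
all-non-branching population of the same density.
"""

from dataclasses import replace

import numpy as np

from axonsim import crowded_cylinder, run_population
from axonsim.metrics import traveled_distance

d, p_b, n_seeds = 0.1, 0.2, 12

cfg0 = crowded_cylinder(num_ax=100, d=d, p_b=p_b)
singleton = replace(cfg0.base, branching=replace(cfg0.base.branching, p_b=0.0))

fails, traveled = 0, []
for seed in range(1, n_seeds + 1):
    res = run_population(replace(cfg0, overrides={0: singleton}), seed=seed)
    fails += int(not res.elongated[0])
    traveled.append(traveled_distance(res.trees[0]))

base = []
for seed in (101, 102, 103):
    res = run_population(crowded_cylinder(num_ax=100, d=d, p_b=0.0), seed=seed)
    base.append(1.0 - np.mean(res.elongated))

print(f"singleton non-branching axon: {fails}/{n_seeds} runs failed "
      f"({100 * fails / n_seeds:.0f}%)")
print(f"all-non-branching population: {100 * np.mean(base):.0f}% failed")
print("traveled distances (um):", " ".join(f"{t:.0f}" for t in sorted(traveled)))
print()
print("The bimodal traveled-distance pattern mirrors single mutant axons that")
print("cannot branch growing in a wild-type population.")
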