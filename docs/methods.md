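# Methods

`axonsim` simulates the growth of axonal populations in three dimensions and
estimates the growth parameters back from morphologies.  This note records
the model, its assumptions, the numerical choices, and what the packaged
tests do and do not establish.

## Single-axon growth kernel

An axonal path is a chain of straight steps of fixed length Δρ.  Step *i* is
described by its spherical angles: azimuth ϑᵢ in the xy plane and elevation
φᵢ toward z.  Each angle is first re-expressed relative to the local
direction of an external attractive field ψ and mapped onto the real line by
the tangent transform

    θᵢ = tan((ϑᵢ − ψᵢ₋₁) / 2),

with ψ evaluated at the step's start point and the difference wrapped into
(−π, π).  In the transformed variable the conditional law of each step is an
ordinary Normal,

    θᵢ | θᵢ₋₁ ~ N( γ θᵢ₋₁ , σ₀² ),   γ = α/(α+β),   σ₀² = 1/(2(α+β)),

where α weighs directional memory (axon rigidity) and β the attraction
toward the field.  The transform avoids von Mises distributions and their
Bessel-function normalizations while keeping the angular domain consistent.
Azimuth and elevation evolve as two independent copies of this chain and
share (α, β) by default (separate elevation weights can be set).

The chain is AR(1), so closed forms exist for the variance after M steps,
σ₀²(1−γ²ᴹ)/(1−γ²); its stationary limit σ₀²/(1−γ²); and the stationary
variance of increments 2σ₀²(1−γ)/(1−γ²).

**Angle conventions.**  ϑ−ψ and φ−ψ₀ are wrapped into (−π, π) before the
transform; the measure-zero singularity at ±π returns a signed sentinel of
10⁸ (a probability-zero event in the continuous model).  Elevation is *not*
clamped to [−π/2, π/2]: the transform itself controls the domain.  As a
consequence the generative chain can momentarily leave the canonical
spherical chart; path-based angle extraction canonicalizes, which matters
only for near-isotropic parameter settings.

**Initial direction.**  A new axon starts aligned with the field at its seed
point (θ₀ = 0); newborn branches draw their first direction from the branch
angle law ω.

**Renormalization.**  Subsampling the AR(1) chain every m steps yields
another AR(1) chain with coefficient γᵐ and the same stationary variance,
which gives coarse-scale parameters

    γ′ = γᵐ,  σ₀′² = σ²_θ∞ (1−γ′²),  α′ = γ′/(2σ₀′²),  β′ = 1/(2σ₀′²) − α′.

This is exact for uniform fields; for spatially varying fields it ignores
field re-evaluation between sub-steps and is an approximation.  Simulation
checks (subsampled fine chain vs. chain generated at the coarse scale)
agree within Monte-Carlo error.

## Time, interactions, and the growth/retraction cycle

Time is algorithmic: in each time unit t_j every axon tip may advance up to
n_max steps (maximum speed n_max·Δρ per time unit).  Axons are hard tubes of
diameter d.  A candidate step is accepted only if the whole candidate
segment (previous tip → candidate point) stays at least d away from every
other deposited segment, inside the cavity, and at least d clear of its
walls.

The candidate *segment* — not just the candidate endpoint — is tested.  A
point-only test admits configurations where two segments cross with all
endpoints clear of d but interiors overlapping, which would violate the
hard-tube picture; the segment test makes the deposition-time rule imply the
global invariant that no two retained non-contiguous segments of distinct
branches are ever closer than d (audited post hoc with a 10⁻⁶ µm
tolerance).  Segments sharing a node with the candidate (the tip's own tail,
and the parent's segments adjacent to a branch origin) are exempt, as are
the last max(n_r, 2)+1 nodes of the growing tip.

On hitting an obstacle the tip withdraws the blocked candidate and retracts
min(n_r − 1, steps made this t_j) previously realized steps — the blocked
candidate counts as the first of the n_r retracted steps — then re-tries
with fresh draws from the same conditional law (no deterministic
deflection).  A second obstacle within the same t_j stops the tip until
t_j+1.  Retraction never crosses a time-unit boundary.  A tip that ends a
time unit with fewer than n_max net steps has its trial counter incremented
by two; it stops for good when the counter exceeds counter_max, which also
guarantees termination of every run.  Each axon draws all randomness from a
substream keyed by (seed, axon id) and axons are iterated in fixed index
order, so runs are bit-reproducible.

**Seeds.**  Entry points are dart-thrown on the entry face, pairwise at
least d apart and d clear of the wall; each unstarted seed is protected by a
zero-length marker segment so later axons cannot wall it in closer than d.

## Branching

Two branch classes are modelled, split at a 10 µm final length in all
morphometrics.

*Type I* (long, stable) branches grow by the same kernel as the main axon.
They appear at the end of a time unit either **at random** — with
probability P_b, at a uniformly chosen step of that time unit — or **upon
contact** — after two mechanical obstacles within one time unit, at the
current tip.  Both routes pass a density gate: the branch is accepted with
probability equal to the Poisson(λ_b) CDF at the (floored) distance from the
tip to the nearest existing branch point.  This is exactly the probability
that the distance exceeds a Poisson(λ_b) random number, reconciling the two
printed forms of the rule; the gate is applied to contact-triggered branches
as well (a single λ_b).  The maximum branch order b_l limits which branches
may spawn further type I branches.  An optional Normal(mean, sd) law caps
individual branch lengths (negative draws truncated at 0).

*Type II* (short, dynamic) protrusions are placed by the Poisson-distance
rule, with lengths drawn from 0.8·U[2,5] + 0.2·U(5,10] µm.  (The observed
split is 80%/18% with 2% unaccounted; the residual is folded into the upper
component to keep the stated [2, 10] µm support.)  They carry no excluded
volume, re-orient uniformly at random every time unit, stabilize permanently
if their tip comes within d of another branch's tip or branch point, and are
removed at the end of the simulation if still transient.  Their per-time-unit
appearance/disappearance statistics are not quantified in the source data;
the default lifecycle (re-orient each t_j, persist as a candidate until
stabilized or lost) is a package choice and is configurable.

## Stopping rules

A neuron stops growing when (i) one of its tips enters the stopping region
(the last 10% of a cylinder, or a ~20 µm end region of a lobe) — this stops
*all* tips of that neuron, and the neuron counts as elongated; (ii) a tip
reaches the maximum traveled distance X_max (x-projection from the entry
point) — also arbor-wide, since a per-tip-only cap lets weakly field-coupled
branches wander without bound; or (iii) a tip's counter is exhausted (that
tip only).  Elongation is classified purely geometrically afterwards: some
tip reached the stopping region.

## Parameter estimation

Each reconstructed or simulated axon yields tangent-variable sequences
(azimuth and elevation pooled by default) from its main root-to-tip path,
resampled to Δρ arc-length spacing.  Sample variances of the sequence and of
its increments give

    γ̂ = 1 − σ̂²_Δθ/(2σ̂²_θ),  σ̂₀² = σ̂²_θ(1−γ̂²),
    α̂ = γ̂/(2σ̂₀²),          β̂ = 1/(2σ̂₀²) − α̂,

valid when γ̂ ∈ (0, 1) and σ̂₀² > 0; degenerate inputs are flagged rather
than returned.  The estimator assumes long, stationary, interaction-free
chains.  Collisions break the chain and bias α̂ downward (verified as a
directional property in the tests), motivating **context calibration**: over
a grid of (α, β), populations are simulated under the study conditions,
per-axon estimates recomputed, and each grid point scored by the sum of two
Kruskal–Wallis p-values comparing the simulated α̂ and β̂ distributions with
the data's.  The score surface is smoothed by a least-squares quadratic
before taking the grid argmax (raw argmax of a p-value sum is noisy); ties
break toward the smallest α+β.  Both the test statistic and the smoothing
are configurable.

The branching probability is estimated as the mean type I branch count per
axon divided by the mean number of time units needed to grow the mean
main-axon length (mean length / (n_max·Δρ)).  λ_b is fit as the mean
inter-branch-point distance.

## Presets and the scale-down used in tests

Packaged presets carry the reference parameter values: the γ-neuron
population (α 7.45, β 1.67, Δρ 1 µm, P_b 0.15, λ_b 6.2, d 0.23 µm, n_max 6,
n_r 2, counter_max 140, X_max 70 µm), the crowded cylinder (α 9, β 2,
λ_b 15, radius 13 µm at 400 axons), and two single-neuron morphology presets
(zebrafish retinal ganglion cell, human cortical pyramidal neuron).  The
medial lobe is represented by a parametric tapered tube (radius 10 → 5 µm
over 70 µm) rather than an anatomical mesh, and the attractive field by a
uniform axial field; quantities tied to the exact anatomical geometry are
therefore treated as qualitative.

Population tests run a **density-matched scale-down**: 100 axons in a
radius-6.5 µm tube, preserving the axons-per-cross-section of the 400-axon
reference condition, with six fixed seeds per condition (the smallest
branching effects are a few percentage points, below the spread of a
three-seed average).  Wall effects are relatively larger in the narrower
tube, so absolute failure percentages shift relative to the full-scale
condition even though every directional effect (failure rising with
diameter and axon count, branching rescuing elongation at moderate density,
out-competition of a non-branching singleton with a bimodal traveled-distance
profile) is preserved.  The out-competition check runs at d = 0.1 µm, where
the scaled cylinder reproduces the reference baseline failure (~10–15%) of
an all-non-branching population; at higher densities the baseline itself
dominates and the contrast inverts.

## What the synthetic data do and do not show

All test inputs are generated by the simulator itself (interaction-free
chains for estimator checks, populations for the collective experiments).
They share the model's own assumptions — fixed step length, independent
azimuth/elevation chains, hard-tube exclusion, algorithmic time — so passing
tests demonstrate internal consistency, correct closed forms, and the
emergence of the collective effects from the stated rules.  They do not
validate the model against real reconstructions: no imaging-derived data are
packaged, coordinate normalization of real lobes is out of scope, and the
inter-tree (ESA) similarity metric used for that comparison is not
implemented (hooks only).

## Known limitations

* Segment-vs-segment exclusion is enforced for the candidate step only;
  already-deposited geometry is never re-checked (it does not need to be —
  deposition is the only way geometry enters).
* The tapered-tube lobe and uniform field are parametric stand-ins; absolute
  elongation percentages in the γ preset are not comparable to values
  obtained with the anatomical geometry.
* Type II branch dynamics are intentionally minimal (no volume, single
  chord, uniform re-orientation).
* The renormalization ignores field curvature between sub-steps.
* Branch initial angles that are near-parallel to the parent are effectively
  suppressed in dense configurations because their first segments cannot
  clear one diameter; this truncation of ω is a consequence of hard-tube
  exclusion, not a separate rule.
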