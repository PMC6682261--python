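# Methods

This note documents the models implemented in `somasim`, the
assumptions baked into each, the defaults and why they were chosen,
and what the test suite does and does not demonstrate.

## Analytic growth model

The per-cycle growth factor r = (1 + αa)(1 − βb) treats one division
cycle as two independent stages: a division stage in which each cell
divides with probability αa (so a cohort of N cells becomes N(1 + αa)
in expectation) and a mortality stage in which each cell dies with
probability βb. All four parameters live in [0,1]; r therefore lives
in [0,2], reaching 2 only at full resources, full efficiency and zero
effective lethality. The model is deterministic — r is an expected
growth factor, and trajectories N₀·rᵏ are real-valued expected counts,
not integer realizations. Stochastic realizations of the same
birth/death process are the job of the lattice simulation, and the
agreement between the two is itself a test (see below).

Survival means r ≥ 1, equivalently βb ≤ αa/(1 + αa). Because the
right-hand side is bounded by ½, full exposure makes every lethality
above 0.5 unsurvivable regardless of (a, α); `critical_lethality`
returns the boundary b* = αa/((1+αa)β), clamped to [0,1], and returns
the string sentinel `"always_survives"` instead of infinity when β = 0
so that outputs stay JSON-serializable.

Boundary handling: `survival_condition` uses a 1e-12 absolute
tolerance so the exact boundary (e.g. βb = 0.5 at αa = 1) counts as
survival, matching the r ≥ 1 definition under floating-point
arithmetic.

## Prediction-error cell model

The toy dynamics couple a cell to a uniformly random environment,
a(t+1) = β·e(t), with the homeostatic prediction p(t+1) = a(t). Under
these dynamics the mean prediction error is proportional to β — full
protection makes the cell's world perfectly predictable. The aggregate
error over d dimensions uses the max norm, because a failure in any
single dimension is lethal: only the worst component matters.

The death rule is deliberately calibrated rather than emergent: a cell
dies in a cycle iff u < β·Δ_lethal with u ~ uniform[0,1], which makes
the per-cycle death fraction exactly β·Δ_lethal by construction. The
raw trajectory rule "die when Δ(t) > Δ_lethal" would give a death
fraction that depends on the distribution of e(t) (for uniform e the
error |β e₁ − β e₂| has a triangular distribution), not the stated
product form; the calibrated rule keeps the death fraction identical
to the analytic model's βb while the trajectory machinery remains
available for property tests. `simulate_death_fraction` is the
Monte-Carlo check that the empirical frequency matches.

Multidimensional survival multiplies per-dimension survival
probabilities (dimensions are independent by assumption), and the
failure-mode count is 2^d − 1 — all non-empty subsets of dimensions
can jointly fail. The subset-enumeration reading was chosen over
2^(d−1) because it is what counting distinct lethal combinations
actually gives; the independent oracle in the tests enumerates
discretized environments and agrees exactly.

Buffer economics share a single load formula, load = β′·Δ_lethal, with
the death fraction. Feasibility fails at load ≥ 0.5·αa (the protector
must then be replaced so often that all resources go to protection and
the protected cell is still periodically exposed); population survival
additionally needs load ≤ αa/(1+αa). The protected growth rate
r^((n/m)(m−k)) uses a real-valued exponent so n need not be a multiple
of the maintenance period m.

## Lattice simulation

Geometry: 30 rows × 60 columns (1800 sites), column j carrying
lethality b_j = j/(cols−1), endpoints exactly 0 and 1; the
high-lethality half is the 900 sites in columns with b > 0.5.
Occupancy counts both stem and somatic cells. Stem cells are seeded
independently per site at 5% density.

Update rule, per cycle:

1. **Death (synchronous).** Neighbor counts are frozen at cycle start.
   A stem cell dies with probability b_j · β_soma^s, where s is its
   somatic-neighbor count; a somatic cell with
   b_j · (1 − resistance) · β_soma^s. Protection compounds
   multiplicatively per somatic neighbor so that a single fully
   protective neighbor (β_soma = 0) already gives complete protection
   and additional protectors never hurt.
2. **Division (sequential).** Surviving stem cells are visited in a
   uniformly random order. A cell with at least one empty neighbor
   divides with probability clamp(α·a, 0, 1), where α compounds
   ×(1 − 0.2) per stem neighbor and ×(1 + 0.2) per somatic neighbor
   (defaults; both adjustable, and an additive dialect
   α = (1 − 0.2·s_stem)(1 + 0.2·s_soma) is available via
   `modifier_mode`). The daughter takes a uniformly random empty
   neighbor immediately, so later dividers in the same cycle cannot
   claim it, and is somatic with probability `p_somatic`.

Dialect choices where the rules are genuinely open: the neighborhood is
Moore (8 neighbors) by default, matching the protective-shell picture
of a stem cell surrounded by somatic progeny, with von Neumann
available; modifiers compound multiplicatively because that form never
goes negative and composes cleanly; the boundary is non-periodic (edge
sites have fewer neighbors) because wraparound is meaningless across a
lethality gradient. Defaults for the parameters without a canonical
value are β_soma = 1 and p_somatic = 0, i.e. the stem-cells-only
baseline; the named experiments override them per condition.

Determinism: a run is a pure function of its config (including
`rng_seed`); sweep replicates derive their seeds as
`rng_seed + value_index * runs_per_value + replicate`, so the 10-run
averages are exactly reproducible.

**Agreement with the analytic model.** On a uniform-lethality grid
with sparse seeding (0.5%), no somatic progeny and the competition
modifier disabled, the pooled early growth factor over the first three
cycles matches (1 + αa)(1 − βb) within Monte-Carlo error. The
competition modifier must be disabled explicitly in this comparison:
daughters are always placed adjacent to their parents, so stem-stem
competition bites from the second cycle at *any* seeding density —
sparseness alone does not make neighbor interactions negligible. With
competition on, early growth is measurably below the analytic value;
with it off, agreement is within one standard error across the (a, b)
grid tested.

## Markov-blanket percolation

A blanket graph has disjoint input (environment-facing) and output
(cell-facing) node sets and binary directed edges; weighted dependency
matrices are thresholded to binary before analysis (dependencies below
the coupling threshold transmit nothing). Transparency uses the
existential reading — some directed input→output path exists — because
protection requires severing *all* paths, so opacity must mean "no
path at all". The universal reading (every input reaches some output),
which corresponds to full exposure β = 1, is exposed as
`strict=True`.

`min_links_to_opacity` reduces to a super-source/super-sink minimum
edge cut with unit capacities on real edges, and is verified
exhaustively against brute-force subset removal on small graphs.
`path_count` enumerates simple paths with a cap so dense graphs stay
bounded; it is offered as a proxy for transmission strength, with no
claim of a quantitative mapping from path count to effective exposure.

Random blankets come in three topologies: `one-to-one` (input i may
link only to output i — one specialist protector per threat),
`layered` (inputs → one intermediate layer → outputs) and `long-range`
(layered plus direct input→output shortcuts). Percolation curves are
Monte-Carlo transparency fractions over an edge-probability grid, and
the threshold is the linear interpolation of the first upward crossing
of 0.5 (reported as not bracketed when the curve never crosses). The
one-to-one topology admits the closed form
P(transparent) = 1 − (1−p)^n, which the tests use as an independent
check; the ordering threshold(long-range) < threshold(layered) <
threshold(one-to-one) is the quantitative content of the claim that
specialist blankets are easier to render opaque.

## Experiments and problem sizes

The named experiments fix the canonical conditions: `figure5a`
(a = 1.0, stem only), `figure5b` (a = 0.8, 50% somatic progeny,
β_soma = 0.5, 50% resistance), `figure5c` (a = 0.8, 50% progeny,
β_soma = 0, 20% resistance), `figure5d` (a = 1.0, 25% progeny,
β_soma = 0, 50% resistance), each 120 cycles. `figure6` sweeps the
protection factor 1 − β from 0 to 1 with 10 runs per value, using
a = 0.8, 50% somatic progeny and the default 20% resistance (the
sweep's source describes "all other parameters as in" the single-run
conditions without naming a panel; this combination is the one whose
non-sweep parameters are shared across panels b/c). The trend test
pools the runs and requires Spearman ρ > 0 at p < 0.01; in practice
ρ ≈ 0.9 with p ≈ 10⁻¹⁹.

Test problem sizes were chosen to give comfortable statistical margins
at interactive runtimes: 10 seeds for occupancy means, 100 runs × 3
cycles for the branching-process comparison (≈ 3000–4500 parent cells
per condition), 10⁵ trials per point for the death-fraction grid, 200
replicates per grid point for percolation curves, and exhaustive
brute-force verification on graphs of up to 12 edges.

## What the synthetic conditions do not show

All inputs are generated internally; nothing here is fit to biological
data. The lattice emulates a static, spatially smooth lethality
gradient with synchronized generations, identical cell parameters, no
mutation or evolution of α, β or `p_somatic` within a run, no motility,
and no cost for switching between stem and somatic fates. Passing
tests therefore demonstrate the internal consistency of the models and
the claimed qualitative transitions (midline blockade, protected
invasion, monotone protection response, percolation ordering) — not
that real proto-metazoan populations crossed the transition this way.
The percolation model likewise treats information transmission as
binary and memoryless; it makes no claim about measured conditional
dependencies in any real signaling network.
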