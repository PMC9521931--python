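# Methods

## Model

Two symmetric 2×2 stage games are coupled through conditional strategies.
The first stage is a Prisoner's Dilemma (`S < P < R < T`, `T + S < 2R`);
the second ("game B") has actions down (d) and up (u) with payoffs `R_B`
(mutual d), `P_B` (mutual u), `T_B` for u-against-d and `S_B` for
d-against-u.  A composite strategy `abc` fixes the PD action `a` and the
game-B replies `b`/`c` to a perceived cooperator/defector; the eight
strategies are ordered `Cuu, Cud, Cdu, Cdd, Duu, Dud, Ddu, Ddd`.

In the direct-interaction model the composite payoff of `x` against `y` is
`PD(a_x, a_y) + B(reply_x(a_y), reply_y(a_x))`.  In the reputation model
each party misperceives its game-B partner's PD action independently with
probability `η`; the matrix entry is the *exact expectation* over the four
perception outcomes (never sampled), which is what the mean-field dynamics
requires.  `η = 0` reduces the reputation matrix to the direct one
identically, and `η ↔ 1 − η` is equivalent to swapping every strategy's
two replies, which is why all population-level observables are symmetric
about `η = 1/2`.

Game B is classified by strict inequalities — anti-coordination
(`T_B > R_B`, `S_B > P_B`), coordination (`R_B > T_B`, `P_B > S_B`),
dominance (weak dominance with one strict inequality) — and ties map to a
`degenerate` class rather than silently choosing.  In an anti-coordination
game the equilibrium action earning less is *soft*, the other *hard*; with
the convention used throughout, soft = d when `T_B > S_B`.

## Static analysis

Pure Nash profiles are enumerated over all 64 ordered cells with weak
(non-strict) best-reply comparisons, because several of the composite
game's equilibria are weak (e.g. `(Cdu, Cdu)` in the Stag Hunt coupling is
payoff-tied with a `Cdd` deviation).  Payoff comparisons use an absolute
tolerance of 1e−9; with integer payoff tables the float64 arithmetic is
exact, so the tolerance only matters for arbitrary real payoffs.

Symmetric mixed equilibria are found by support enumeration: the
indifference system on a candidate support is solved linearly
(`numpy.linalg.solve` on the bordered system) and the candidate is
accepted only if the weights are nonnegative and no outside strategy earns
strictly more (again 1e−9); rank-deficient systems are reported as
degenerate rather than solved in a least-squares sense.  The printed
closed-form equilibria (the two coordination-class two-strategy fixed
points, the four-strategy anti-coordination equilibrium, and the fully
cooperative family) are provided as *unverified substitutions*: the
matrix-based support solver is the oracle.  The package intentionally
preserves a discrepancy in the two-strategy `Cdd–Ddu` closed form, whose
printed self-interaction term is inconsistent with the composite payoff
table: substitution gives (2/3, 1/3) while indifference on the table gives
(0.6, 0.4).  Both numbers are exposed and the substitution is flagged
unverified.

For the fully cooperative family, indifference fixes only the sums
`x_Cuu + x_Cud` and `x_Cdu + x_Cdd`.  The no-deviation condition is
evaluated directly on the composite matrix; with the base Snow Drift
payoffs it binds through the defectors that play d with cooperators and
constrains `x_Cud + x_Cdd ≤ 1/3 − c/2` (the printed closed-form bound
names `x_Cdu` in place of `x_Cdd`; the matrix check is authoritative here,
and the printed bound is still reported verbatim by the closed-form API).
Either way the family is nonempty iff the cost of cooperation is below
2/3, and `fully_cooperative_cost_threshold` locates that bound by
bisection on the family's least-binding member.

The existence rule for cooperative pure equilibria — cost `P − S` below
`|T_B − S_B|` (anti-coordination) or `|R_B − P_B|` (coordination) — was
verified exactly equivalent to enumeration over 1000 random
anti-coordination couplings.  For coordination-class game B the rule
governs the heterogeneous cooperator–defector equilibria; the
mutual-cooperation profile requires `T − R` below the same gap instead, so
the rule is exact whenever `P − S = T − R` (helping game, base presets) but
only sufficient-in-one-branch for arbitrary PDs.

## Mean-field dynamics

The discrete-generation replicator–mutator map is
`ρ_x(t+1) = Σ_y ν_{x,y} ρ_y π_y / π̄` with `ν_{x,y} = ν/7` off-diagonal and
`π = π₀ + A ρ`.  Payoffs act as reproduction weights, so they must be
nonnegative: the configuration object verifies `π₀ + min(A) ≥ 0` at
construction (the minimum over the simplex of a linear payoff is attained
at a vertex).  A zero payoff is permitted for a strategy with zero
frequency — this arises at monomorphic boundary states — but a negative
payoff, or a nonpositive payoff for a strategy actually present, raises an
error naming the strategy and suggesting a larger `π₀`.  `π₀` defaults to
0 (adequate for the all-nonnegative preset tables) and must be set
explicitly (e.g. 5) for helping games, whose sucker payoff is negative.

Convergence is declared when the L1 step residual falls below 1e−12
(default; at most 10⁶ iterations), and non-convergence — including cycles
— is reported, not averaged away.  States are labelled by a
mutation-pressure floor: defective if `ρ_C ≤ 10ν`, fully cooperative if
`ρ_D ≤ 10ν`, cooperative otherwise; the floor is a parameter.  Stability
is assessed by finite-difference differentiation of the step map along the
in-simplex directions `e_i − ρ*` and restriction of the Jacobian to the
sum-zero tangent space; the fixed point is stable iff the spectral radius
is below `1 − 10⁻⁶`, and near-unit eigenvalues are reported as neutral
directions (this is how the mutual-u defective state of the Stag Hunt
coupling shows its neutral `Duu → Dud` direction).

Basins are estimated from flat-Dirichlet (uniform) samples of the
8-simplex — the sampler is pluggable since uniformity is a modelling
choice — with binomial standard errors, optionally binned by the initial
cooperator or soft-play density.

Two finite-mutation artefacts matter and shaped the defaults:

- *Cost-only dependence.*  Replacing the helping-game benefit `b` by
  `b + Δb` shifts every strategy's payoff by `Δb·ρ_C`, which leaves
  replicator fixed points invariant only at `ν = 0`; at `ν > 0` the
  mutation inflow does not rescale and displaces the fixed point by
  `O(ν·Δb/(1−λ))` (measured: 1.1e−6 at `ν = 10⁻⁷`, 1.1e−7 at `10⁻⁸`,
  linear as derived).  The benefit-independence check therefore runs at
  `ν = 10⁻⁸`, where the distortion sits two orders below the 1e−6
  comparison band, and at cost 0.8 — inside the coexistence regime, where
  the fixed point is isolated.  Below cost 2/3 the fully cooperative
  family is *neutral* at `ν = 0`, its relaxation time scales like `1/ν`,
  and a tight stationary-state comparison is ill-posed.
- *Fully cooperative phase detection.*  For the same reason the mutant
  load near the fully cooperative family is an order of magnitude above
  the usual `~ν` scale (10–50ν measured across costs), so a raw `10ν`
  floor would misplace the phase boundary at any mutation rate.  The cost
  sweep (`fully_cooperative_sweep`, run at `ν = 10⁻³`, `π₀ = 5`, benefit
  2) therefore measures the stationary defector density at `ν` and `ν/2`
  and labels by the Richardson extrapolation `2ρ_D(ν/2) − ρ_D(ν) ≤ 10ν`,
  which cancels the linear-in-ν load and recovers the zero-mutation phase
  structure; the measured transition sits at `c ≈ 0.62`, within 7% of the
  exact 2/3 bound (the residual bias is the `√ν` critical smearing at the
  continuous transition).

## Finite populations

The agent-based model uses synchronous Wright–Fisher generations: one
uniform random perfect matching per stage (the same matching for both
stages in the direct model, independent matchings with per-encounter
perception flips in the reputation model), payoff `π₀` plus the realized
stage payoffs from exactly one PD partner and one game-B partner — the
sampling noise is retained on purpose — and whole-population resampling
with probability proportional to payoff, followed by mutation to one of
the other seven strategies with probability `ν`.  The generational
(rather than Moran) update matches the discrete-generation mean-field
map, and one resampled generation agrees with the replicator step within
three standard errors at `N = 10⁴` over 200 replicates.  Observables that
involve game-B behaviour (`ρ_d`, `Δπ`, the correlation) are computed from
the *realized* actions and payoffs of the recorded generation, since
conditional strategies have no unconditional game-B action.

## Structured populations

Individuals sit on an `L × L` torus with von Neumann connectivity, play
both stages with all four neighbours, and synchronously imitate a model
drawn from the 5-member extended neighbourhood with probability
proportional to payoff, then mutate with probability `ν`.  In the
reputation model the two directed perception flips of each encounter are
drawn once per step and shared by both parties' payoffs.  Synchrony is a
modelling choice (documented, switchable fields exist in the parameter
object); imitation uses raw payoffs, which are nonnegative for the preset
tables, with `π₀` available otherwise and a uniform draw (with a logged
warning) in the measure-zero case of an all-zero extended neighbourhood.
One time step = one full-lattice payoff evaluation plus one imitation
pass.

## Problem sizes and defaults

Defaults follow the recurring study conditions: mutation rate `ν = 0.005`,
`η = 0`, `π₀ = 0` for the preset payoffs, base payoff tables PD (3,0,5,1),
Snow Drift (3,1,5,0), Battle of the Sexes (0,3,5,0), Leader (2,3,5,1),
Stag Hunt (5,0,1,1).  The test suite and the acceptance script run at desk
scale, chosen after checking convergence of the quantities involved:
mean-field runs to residual 1e−12; basin estimates with 10⁴ (tests) or
2×10³ (script) samples instead of 10⁷; finite populations of `N = 10⁴` for
3000–4000 generations with a 500-generation tail (the dynamical transition
from random starts completes within ~500 generations); lattices of
`L = 100` instead of 200–400, for 1000–3000 steps.  Larger sizes are plain
parameters.

## What the generator does and does not emulate

All inputs are generated in code from the parameterizations above; there
is no external data.  The synthetic conditions reproduce the model's own
universe — well-mixed or lattice populations with exact payoff tables —
so passing tests validate the mathematics and its implementation, not the
applicability of the model to any empirical population.  Finite-size
effects are represented (and visibly favour cooperation, as the
basin/ABM comparisons show), but demographic structure beyond the square
lattice, asymmetric games, and more than two strategies per stage are out
of scope.

## Known limitations

- The coordination-class existence rule is exact only when `P − S = T − R`
  (see above).
- The bistability boundary of the phase scan is located at grid-edge
  resolution; no sub-grid root finding.
- Near the symmetry-breaking critical point, convergence of the
  replicator map slows and desk-scale runs may report non-convergence;
  those cells are labelled `unclassified` rather than forced.
- The defection-favoring initial family of the scan is 90% `Dud` + 10%
  uniform.  An even spread over the four defective strategies does not
  probe the defective basin: `Ddd`/`Ddu` play softly with cooperators, and
  such compositions already lie in the cooperative basin of
  anti-coordination couplings (low initial cooperator density *favours*
  cooperation in this model).
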