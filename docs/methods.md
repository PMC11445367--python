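# Methods

## Model

The population process is a continuous-time Markov chain on counts
`N ∈ ℕ^V` over a finite directed trait graph `G = (V, E)`.  Per-capita
rates: birth `b(v)`, death `d(v) + Σ_w c(v, w) N_w / K`.  A birth mutates
with probability `μ_K = K^(−1/α)` and lands on `w` with probability
`m(v, w) > 0` iff `(v, w) ∈ E`; `m(v, ·)` must be a probability measure on
the out-neighbours (tolerance 1e−9 on the row sum), traits without
out-edges reproduce clonally.  Standing assumptions enforced at load time:
`c(v, v) > 0`, `α ∉ ℕ` (no subpopulation of critical order `K^0`), and —
checked lazily wherever the calculus branches on a sign — no invasion
fitness within 1e−9 of zero.

Units: rates are time⁻¹; abundances `n = N/K` are densities; exponents
`β_v = ln(1 + N_v)/ln K ∈ [0, 1]` so that `β = 0 ⟺ N = 0`.

## Deterministic ecology

Coexistence equilibria are solved linearly on the support
(`b − d = C n̄`); a singular interaction matrix with a consistent system is
a genuine degeneracy (continuum of equilibria) and is refused, while an
inconsistent one simply means no full-support equilibrium.  Stability is
reported in layers: `verified-locally-stable` / `verified-unstable` from
the Jacobian spectrum at margin 1e−9, upgraded to
`heuristic-globally-stable` when the flow from a deterministic grid of
`2^|support| + 2` perturbed starts (±40 % box corners, a near-extinct and a
high-density point) returns to the equilibrium within 1e−6.  Global
stability is assumed by the theory but undecidable in general, so the ESC
calculus *requires* at least the heuristic verdict and exposes a
`trust_stability` override; nothing in the package ever claims certified
global stability.

## ESC calculus

`V_α`, the stability degree `L`, mutant candidates, the mutation-fed
profile `β_w = (1 − d(v, w)/α)₊` and the equilibrium prefactors

    a_v = Σ_{shortest γ: v→v} n̄_γ0 Π_i b(γ_{i−1}) m(γ_{i−1}, γ_i)/|f(γ_i, v)|

are computed by exact graph enumeration (BFS shortest-path layering with a
configurable cap of 1e5 paths; overflow raises rather than truncates).
The per-path crossing rate is implemented exactly as the product formula in
the README, with the arrival rate (everything but the final fixation factor
`f/b`) exposed separately for testing.  The excursion factor uses the
closed form `λ(ρ) = ρ/(1 − 2ρ)` for `ρ < 1/2`; values for `ρ > 1/2` are
provided through the symmetry `λ(ρ)ρ = λ(1−ρ)(1−ρ)` purely as a
convenience, and `ρ = 1/2` (a critical excursion, excluded by the
no-zero-fitness assumption) raises.  The truncated-series cross-check of
`λ` converges geometrically at rate `4ρ(1−ρ)`; note that at `ρ = 0.4` this
is 0.96, so ~440 terms are needed for 1e−8 agreement — a 200-term partial
sum is only good to ~1.5e−4 there.

## ln K invasion dynamics

Between metastable jumps every exponent is a clamped maximum of affine
functions of time: trait `u`, alive at the phase start or seeded at `t_u`
(the first time an in-neighbour reaches `1/α`), contributes
`β_u(0) + (t − t_u) f(u, v) − d(u, w)/α` to every reachable `w`.  The
implementation is event-driven with closed-form event times — no time
stepping and no step-size tuning; events are macroscopic arrival (`β = 1`),
first `1/α`-crossings (which seed fit out-neighbours; unfit ones need no
own growth term since the feed terms already carry them), extinctions
(`β = 0`), and stabilisation.  Between events each β is exactly affine, so
replaying with a finer tolerance reproduces identical trajectories (tested).

When a trait reaches exponent 1 the Lotka–Volterra flow on
`residents ∪ {newcomer}` is integrated (newcomer density 1e−3, convergence
drift < 1e−10 per 100-time-unit chunk, five perturbed restarts) and the
support of the attained equilibrium becomes the new resident set; restart
disagreement, non-convergence, or an uncertifiable attained equilibrium
terminate the run as `no-unique-lv-equilibrium`.  Other termination
criteria: two macroscopic arrivals within 1e−9 (`simultaneous-events`), a
vanishing invasion fitness (`zero-fitness`), recurrence of a
`(residents, β)` state quantised at 1e−7 without qualifying as an ESC
(`non-convergent-cycle`), and a step limit of `10 |V|²` resident updates.
Revisiting a resident set with a *different* profile is allowed — the
cyclic-dominance example depends on it.  On stabilisation (no fit living
trait and no pending seeding) all transient terms decay linearly onto the
resident-fed profile; the run advances to the last extinction, certifies
the resident set as an ESC and returns it.  With `α < 1` the initial
mutant exponent `min(1/α, 1)` is already macroscopic and the dynamics
reduce to the trait-substitution rule (the seeding threshold `1/α > 1` is
unreachable, correctly disabling mutation-fed growth).

Downstream builders never guess through a terminated run: the affected
node is marked frontier-invalid, its uncertified transitions are omitted,
and time-scale collapses refuse with a witness when such a node (or an
inescapable low-stability class) blocks the passage assumption.

## Meta-graphs and jump processes

Nodes are enumerated over supports up to a configurable size (default 3;
the worked examples need at most pairs — the cap is metadata on the
graph).  The possibly infinite path sum defining the collapsed transition
probabilities `p^L` is evaluated by solving the linear absorption system on
the intermediate (lower-stability) states, which is exact for the geometric
cycle cases; hitting probabilities fall back to value iteration (the
minimal solution) when a closed class makes the linear system singular.
Parallel collapsed edges merge by adding probabilities and rates; edge
metadata retains the contributing candidates.  The limiting process is
sampled as a standard CTMC: exponential holding time with the total
outgoing rate on the `1/(K μ_K^L)` scale, successor proportional to edge
rates, more stable nodes absorbing.

## Stochastic simulator

A direct (non-approximate) Gillespie algorithm, jitted with numba; rates
are recomputed per event (O(|V|²), trivial at the graph sizes in scope) and
mutation targets drawn from precomputed cumulative rows.  Seeds determine
traces exactly; replicates use `seed + replicate_index` on independent
streams, and runs at different `K` are independent.  Fixation is detected
online and event-exactly as the first trait outside `V_α` reaching
`N ≥ K^{1/α} − 1` (exponent `1/α`); ESC arrival is evaluated on a sampling
grid (default 0.1 time units — the quantity only enters at O(ln K)
precision) with corridor `ε_K = C/ln K`, default
`C = 2 max_v |ln a_v| + 1` so the corridor contains the prefactor-shifted
exponents.  ESC-profile initial states place residents at `round(K n̄_v)`
and fed traits at `round(a_v K μ_K^d)`, warning when a count rounds to
zero (the asymptotic profile is meaningless at such K).

### Finite-K validation and what it shows

The exponential law `T_fix K μ_K^L ≈ Exp(R)` is a `K → ∞` statement.  At
desk scale the sample carries a deterministic offset: the fixating lineage
still needs `≈ ln K/(α f(w, v))` time units to grow from one individual to
`K^{1/α}`, which is the first-order bound the theory itself provides for
the conditioned growth phase.  The harness reports both the raw rescaled
times and the growth-corrected ones; at `K = 500` on the width-2 valley
the raw sample is visibly shifted (KS distance ≈ 0.16 from `Exp(1/3)`)
while the corrected sample is statistically indistinguishable from the
limit law (KS ≈ 0.04–0.08 over seeds).  Validation therefore asserts the
mean and KS test on the corrected sample.  Branch-probability validation
uses the valley toys at their default `K = 1000`, where the finite-K bias
of the branch frequencies (~0.02) is well inside the Monte-Carlo band.

Problem sizes used by the validation suite: 200 replicates at `K = 500`
for the exit law, 400 replicates at `K = 1000` for the branching check,
five pooled pre-fixation windows at `K = 1000` (burn-in 5 time units) for
prefactor recovery, and 1e5 Monte-Carlo excursions for the `λ` oracle.

## The fixture landscapes

The seven worked examples are stated in the source material as trait
graphs plus sign/order constraints on fitnesses; the generators pick one
concrete parameterisation per example (recorded in
`fixture_manifest(name)`), with conventions `d = 1`, `b = 1 + r`, `c = 1`
and pairwise-distinct `r` wherever competition is symmetric, so no
invasion fitness can vanish.  Non-transitive fitness relations (the
cyclic-dominance examples) are encoded with asymmetric competition; the
three-trait dominance cycles use a May–Leonard parameterisation (equal `r`
inside the triple, cross-competitions 1.6 and 0.5) whose interior
equilibrium is provably unstable (1.6 + 0.5 > 2), keeping the landscapes
free of polymorphic coexistence as their constraints demand.  One example
requires a timing constraint — the ousted trait must go extinct before the
cycle closes — enforced with margin by `f(4, {5}) = −2` versus
`f(2, {5}) = 0.3` at `α = 1.5`.  The first example's continuation beyond
the second layer is only partially constrained by its source; the fixture
adopts the minimal reconstruction (one terminal branch, two branches
converging on the fittest trait along paths of lengths 1 and 2) and its
manifest flags the chosen numbers.

The generators emulate the study's idealised landscapes exactly; they do
not attempt to model empirical fitness data, and passing tests show
correctness of the calculus on such landscapes, not calibration to any
biological system.

## Known limitations

* Node enumeration over resident supports is capped (default 3) — graphs
  whose ESCs need larger coexistent sets require raising the cap.
* Global stability of LV equilibria is heuristic by construction.
* Ergodic-cluster coarse-graining (escaping a low-scale cycle by pooling
  its stationary distribution) is out of scope; the finite-passage check
  refuses such cases with a witness instead.
* The simulator is exact but serial; desk-scale `K ≲ 10⁴` is the intended
  regime.
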