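# Methods

## The model

`toxinwars` studies how bacteria should regulate toxin-mediated attacks on
competitors. The unit of analysis is a pairwise competition in a well-mixed
patch: two strains A and B grow on one shared nutrient pool and each makes
a toxin that harms only the other strain. Writing `M = N/(N + K_N)` for the
Monod uptake factor, the state (C_A, C_B, T_A, T_B, N) evolves as

    dC_A/dt = (1 - f_A) mu_max M C_A - k T_B C_A
    dC_B/dt = (1 - f_B) mu_max M C_B - k T_A C_B
    dT_A/dt = f_A M C_A - l_T T_A
    dT_B/dt = f_B M C_B - l_T T_B
    dN/dt   = -M (C_A + C_B)

`f_X` in [0, 1] is strain X's instantaneous investment into toxin
production; the cost is allocative (a strain investing f grows at (1 - f)
of its maximal rate). With `k = l_T = 0` the quantity
`C_A + C_B + mu_max (T_A + T_B + N)` is exactly conserved; the test suite
uses this identity as an analytic oracle.

A *strategy* is either constitutive (fixed f) or regulated: production
switches between `f_initial` and `f_induced` when a sensed signal crosses
a threshold (Heaviside switch, H(0) = 1). The three sensed signals are
nutrient depletion `N(0) - N(t)` (threshold U_N), the opponent's toxin
`T_opp(t)` (U_TB, i.e. reciprocation via competition sensing), and the
producer's own biomass `C_own(t)` (U_QS, quorum sensing). `f_induced` may
be below `f_initial` (repression) as well as above it (activation).

### Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| K_N | nutrient saturation constant | 5 | gN |
| mu_max | maximum growth rate | 10 | 1/hr |
| k | toxin killing efficiency | 20 | 1/(gT·hr) |
| l_T | toxin loss rate | 0.1 | 1/hr |
| N(0) | initial nutrient pool | 1 | gN |
| C_A(0), C_B(0) | initial biomass per strain | 0.1 | gC |
| t_end | competition duration | 24 | hr |
| — | extinction threshold | 1e-6 | gC |
| — | state clamp threshold | 1e-8 | — |
| dt | solver step | 0.01 | hr |

Initial toxin is zero: toxin must be produced during the competition.
Both strains seed a patch at equal biomass by default; asymmetric seeding
is exposed through `C0_A`/`C0_B`.

## Numerics

The ODEs are integrated by backward Euler with an analytic-Jacobian Newton
solve per step (residual tolerance 1e-11, max 50 iterations, two half
steps as fallback; Newton rows are frozen at first convergence so results
are bit-identical across batch compositions). Regulated investments are
evaluated from the state at the start of each step and held constant
through it, keeping the discontinuous switch outside the implicit solve.
After each step, any state variable below 1e-8 is clamped to zero, then
any strain below 1e-6 is removed irreversibly (stochastic extinction of a
nearly-empty patch niche); its already-released toxin keeps decaying. The
solver is vectorised over batches of competitions sharing one parameter
set, which is what makes grid tournaments and the genetic algorithm
feasible on a single CPU (a 24 h competition takes 2,400 implicit steps;
batches of a few thousand competitions integrate together).

`dt = 0.01` hr is the production default. Backward Euler is first-order:
against an adaptive reference integrator (`toxinwars.reference`, scipy
LSODA with event-located extinction and switching), final biomasses at
dt = 0.01 deviate by a few percent in the worst cases — final biomass is
a small residual of nearly cancelling growth and killing terms — and the
deviation halves with dt, vanishing at refined steps. The oracle
equivalence test therefore runs its 20-pair panel at dt = 1e-4, where the
deviation is below 1e-3 relative, while the *game-theoretic* outputs
(invasion rankings, the optimal investment, tournament winners) are
verified to be insensitive to dt from 0.1 down to 0.001. The reference
integrator offers two regulation semantics: `interval` (investments frozen
per production step — isolates truncation error) and `event` (threshold
crossings located exactly in time — the mathematically exact hybrid
system, used for the refined-step panel).

Two dynamical regimes are excluded from the oracle panel by design.
Sliding regimes — a quorum strategy whose biomass hovers on its density
threshold while production toggles — make the exact hybrid system chatter;
the event reference detects this and raises rather than returning a
pseudo-solution. Near-annihilation endpoints (final biomasses within a
couple of orders of magnitude of the extinction threshold) amplify
switch-timing quantisation exponentially, so no fixed-step solver can meet
a relative target there; relative deviations are accordingly measured
against a scale floored at ten times the extinction threshold.

## Invasion analysis

A rare mutant's metapopulation fate compares its productivity against the
resident with the resident's productivity against itself:

    I_inv = w(f_inv | f_res) / w(f_res | f_res)

where w(x | y) is the final biomass of the strain playing x in an x-vs-y
patch. I_inv > 1 means the mutant spreads. Local patch success and global
success can disagree (a patch winner that makes few cells; a patch loser
that out-produces the average resident), which the outcome classifier
exposes as four classes plus a neutral/tied residual. Indices within 1e-6
of 1 are treated as "cannot invade" (neutrality band), which keeps the
pairwise-invasibility diagonal exactly neutral. A *stable* invasion also
requires that the displaced resident cannot re-invade from rare.

The ESS search builds the full invasion matrix on a grid of constitutive
investments and applies the two quantifiers directly: f* must invade every
other grid strategy and be invaded by none. Two subtleties arose and are
design decisions of this package:

1. **The passive resident.** A pair of f = 0 residents wastes nothing on
   toxins and converts the whole nutrient pool into cells, so *no*
   strategy out-produces it globally: every producer wins the f = 0 patch
   locally but makes fewer cells than a passive pair does. A strict
   two-sided ESS therefore does not exist on the full grid at the standard
   parameters. `find_ess` reports the strict ESS when it exists (e.g.
   f* = 0 when toxins are harmless, k = 0) and otherwise also reports
   `f_opt`: the non-degenerate strategy invaded by *none* that invades the
   largest number of others. At every parameter set inspected, `f_opt`
   coincides with the convergence-stable singular strategy of the
   near-diagonal invasion pattern — the endpoint of small-step adaptive
   evolution — and it is what sweeps and the acceptance script report.
   At standard parameters `f_opt = 0.31` on the 0.01 grid: it invades all
   100 other strategies and only fails to displace the passive
   non-producer.
2. **Degenerate residents.** Strategies whose resident-vs-resident patch
   self-extinguishes (w_res = 0) make the index undefined; they are
   flagged, excluded from ESS candidacy, and recorded as missing matrix
   columns.

## Tournaments over sensing strategies

The whole-space scan asks which (f_initial, f_induced) combinations admit,
for at least one threshold, a sensing strategy that stably invades every
constitutive producer. The full-resolution grids (f steps of 0.02, threshold
steps of 0.002 over signal ranges up to 20) imply millions of
competitions; the package exposes them via `SensingGridSpec.scan_default`
(with a proportional `scale` coarsening factor) and additionally defines
documented *desk grids* (`desk_scan`, `desk_diversity`): coarse f steps of
0.2 and a geometric spread of thresholds over the same signal ranges,
sized so the full three-mode scan runs in about a minute. Because the
passive f = 0 blocks global invasion for every strategy (above), the scan
reports both `stable_pairs` (strict: the entire grid) and
`stable_producer_pairs` (every producing opponent, f > 0) — the latter is
the informative notion, and each sensing mode has a non-empty region of
universally invading regulators: low f_initial, induced investment around
0.4–0.8, thresholds early in the signal range. Encounters where both
directions invade are recorded as mixed evolutionary outcomes; across the
desk scan about 3% of successful invaders are re-invadable.

The standing-diversity tournament optimises each sensing mode against the
five reference opponent sets ({0.5}, {0.4–0.6}, {0.3–0.7}, {0.2–0.8},
{0.1–0.9}), fitness being the mean final biomass across the set (sums and
means rank identically at fixed set size; ties break lexicographically
toward lower parameters). The per-competition fitness of the winners feeds
an OLS regression `F ~ alpha_S + beta D` with a two-level toxin-vs-other
type indicator and the number of opponents D as a numeric covariate. The
"x-times higher fitness" summary of such an analysis does not pin down which ratio is
meant, so the model reports both the intercept ratio and the ratio of
fitted group means at the mean diversity level, along with the p-value of
the type coefficient. At the desk grids, toxin sensing wins every
diversity level, with a mean-fitness ratio near 2.7 (p < 0.001); at
t_end = 6 hr the advantage disappears — with no time to profit from
switching off after victory, reciprocation loses its edge.

## Genetic algorithm

Populations of n = 60 strategies (desk runs: n = 30) evolve by round-robin
evaluation — every strategy competes against all n, including a clone of
itself, and sums its final biomasses — followed by the generation update:
the top 4 carry over unchanged, 36 fitness-proportional draws get exactly
one uniformly chosen parameter perturbed by N(0, 0.001) (the perturbation
is redrawn until the constraint box f in [0,1], U_N in [0,1], U_TB in
[0,4], U_QS in [0,1.2] is met; after 1,000 attempts it is clipped and
logged), and 10 fresh uniform immigrants are added. Counts scale
proportionally for other population sizes. Mixed three-type tournaments
begin with a burn-in (20 generations by default) in which the whole
population is replaced by immigrants each generation — no selection — so
type frequencies start neutral; immigrants during selection are fully
random (type drawn uniformly first). One master seed derives four
independent sub-streams (initialisation, selection, mutation,
immigration), so changing one stage's draw count does not perturb the
others. Reported optima are the mean parameters of the top 4 strategies
(the 5%-fittest alternative is exposed via `top_k`).

Reduced within-type runs (n = 30, 40 generations, three fixed seeds)
reproduce the qualitative ordering of induced aggression — toxin sensing
evolves the strongest response, quorum sensing intermediate, nutrient
sensing the weakest — and the toxin-sensing equilibrium is the
reciprocator (near-zero initial investment, strong induced response) whose
self-play never triggers production. One genuine divergence from the
upregulate-after-delay picture: in this model the nutrient-sensing
within-type equilibrium is a *downregulator* (start aggressive, shut off
once nutrients deplete); direct two-way invasion analysis confirms the
downregulator stably displaces the upregulating variant and cannot be
re-invaded. See the limitations note below.

## Scenarios and sweeps

Parameter sweeps use factor ladders (×/÷2 and ×/÷4 around the standard
values) — direction-of-change claims need direction only. The initial
nutrient ladder instead uses {1/16, 1/4, 1, 4}× because the optimal
investment peaks near a quarter of the standard pool, and a ladder must
bracket that interior maximum to resolve its rise-then-fall shape. The
measured directions: the optimum rises with killing efficiency k,
saturation constant K_N and seeding density C(0); falls with maximum
growth rate mu_max and toxin loss l_T; and has the interior maximum in
N(0). The fixture corpus (`make_fixtures`) covers the qualitative regimes
— unequal constitutive duel, conservation pair, each sensing mode against
the optimal constitutive producer, a quorum downregulator, reciprocation
with post-victory disarmament, an extinction-triggering pair — each with a
machine-checked expectation.

## Known limitations

- Patches are well mixed; within-patch spatial structure (and therefore
  position-dependent sensing) is out of scope, as are multiple toxins or
  resistance evolution per strain.
- The metapopulation layer is implicit: invasion indices summarise the
  seeding–competition–dispersal life cycle rather than simulating patches
  explicitly, so frequency-dependent coexistence inside a patch is not
  represented.
- Regulation is a sharp two-level switch; graded dose-response regulation
  is not modelled.
- Backward Euler at the production step size carries percent-level
  absolute biomass error (documented above); all comparative results are
  verified to be step-size robust, but absolute biomasses at dt = 0.01
  should be read with that accuracy in mind.
- The desk grids and reduced tournament sizes trade resolution for
  single-CPU runtimes; the full-resolution grids remain available through the
  grid constructors and the CLI `--scale` flag, and sharper grids can only
  enlarge the reported stable-invasion regions (threshold supersets never
  remove solutions).
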