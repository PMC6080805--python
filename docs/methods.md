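# Methods

## Scope and model

`crossfeed` asks how many distinct cross-feeding niches a metabolism can
construct: pairs of a *primary* carbon source (consumed from the feed) and a
*secondary* carbon source (excreted as a by-product, consumed by a second
strain).  All computations are constraint-based: a metabolism is a
stoichiometric matrix `S` with flux bounds `l ≤ v ≤ u`, and flux balance
analysis (FBA) maximizes the biomass flux subject to the steady-state
constraint `S·v = 0`.  Growth or production fluxes below
`ε = 1e-5 mmol gDW⁻¹ h⁻¹` are treated as zero throughout; the LP backend is
GLPK via cobrapy/optlang, and only objective values are contractual (flux
vectors may be degenerate and are never asserted in tests).

## Media

A minimal medium is a set of freely available inorganic nutrients plus
explicit carbon sources with bounded uptake.  The *E. coli* mineral set
contains ammonium, calcium, chloride, cobalt, copper, iron(II/III),
magnesium, manganese, molybdate, nickel, oxygen, phosphate, potassium,
protons, sodium, sulphate and zinc; water is additionally exchanged freely in
both directions (a model cannot run without water transport, and water
carries no carbon).  Presets for *B. subtilis* (CO₂ available; ammonium,
phosphate, sulphate ≤ 5) and *S. cerevisiae* (oxygen ≤ 2) are included.
Internally uptake is a negative exchange flux; every user-facing rate is a
positive magnitude.

## Carbon-source screens

* **Primary screen** — every exchanged metabolite with ≥ 1 carbon atom is
  offered as the sole carbon source with uptake allowed up to
  10 mmol gDW⁻¹ h⁻¹; it is a primary source iff the biomass optimum exceeds
  ε.  The uptake bound matters: on iJO1366 the screen yields 180 primaries at
  a bound of 10 but 181 when unbounded.
* **Production screen** (`can_produce`) — primary uptake fixed at exactly 10,
  biomass required above ε, export of the candidate secondary maximized.
  Candidates are restricted to the primary-source list: a useful secondary
  must itself sustain growth.
* **Maximal production rate** `p_max` — the export rate beyond which a
  producer growing at the dilution rate D washes out.  Computed by fixing
  growth at D and bounding primary uptake by the Michaelis–Menten transport
  limit *at the feed concentration*, `Vmax·M⁰/(kM+M⁰) = 19.05` for the
  reference 1 mM glucose feed: at the washout limit producer biomass
  vanishes, so the ambient concentration equals the feed concentration and
  transport is the binding constraint.  CO₂ uptake is left open in this
  screen (re-fixing respiratory CO₂ matters for highly oxidised products
  such as formate, whose maximal production exceeds the glucose carbon input
  alone); CO₂ cannot serve as a carbon source by itself, so this does not
  affect viability verdicts.
* **Biomass yield** `α = D/u*` with `u*` the minimal uptake of the carbon
  source (as sole source) that sustains growth exactly at D.  For a linear
  pathway α is the stoichiometric yield, independent of D.
* **Production cost** — the secant `(μ₀ − μ(p))/p` at p equal to 1% of the
  pair's production optimum, at fixed primary uptake 10.  Used only for
  ranking; for the analytic fixture it equals the hand value 0.1 h⁻¹ exactly
  and is step-size independent.

## Chemostat dynamics (dynamic FBA)

Strain biomasses `X_s` (gDW/l) and metabolite concentrations `M` (mM) evolve
by explicit Euler steps of `dt = 0.1 h`:

1. **Uptake bounds.**  Each strain's uptake of each dynamic nutrient is
   bounded by `min(Vmax·M/(kM+M), availability)` with
   `Vmax = 20 mmol gDW⁻¹ h⁻¹`, `kM = 0.05 mM`.  The availability limit caps
   total consumption per step at the standing pool `M/dt`.  When several
   strains compete for one pool it is shared by **max-min fair
   water-filling** over per-strain demands `min(cap, transport limit)` with
   biomass-proportional base shares: a strain whose demand is below its fair
   share takes its full demand and the remainder goes to the strains that can
   use it.  This scheme was chosen because its fixed point is exactly the
   continuous competitive equilibrium (capped consumers unrationed, the
   uncapped strain marginal).  Two alternatives are available as
   `ChemostatConfig.allocation` options: `"consumption"` (shares proportional
   to the previous step's realized consumption, with a small floor) and
   `"biomass"`.  The consumption scheme turns *every* allocation into a
   neutrally stable fixed point once a shared resource becomes scarce —
   shares freeze at whatever ratio existed when scarcity set in — and can
   trap a forced producer in a starvation spiral, which is why it is not the
   default.
2. **FBA per strain.**  Independent growth-maximizing LPs give `μ_s` and all
   exchange fluxes `J_{M,s}`.  A producer's phenotype is an export floor `p`
   on its secondary's exchange reaction (the LP may exceed it, but never does
   at an optimum because export is costly); a consumer's phenotype is an
   uptake cap `c` on the primary.  If the export floor is infeasible under
   the step's uptake bounds, it is relaxed to the maximal achievable export
   before declaring starvation — a cell cannot excrete substrate it never
   took up.  Without this relaxation the all-or-nothing infeasibility
   produces a period-2 limit cycle (consume nothing → substrate accumulates →
   overshoot).  Washout behaviour is unaffected: achievable export implies
   μ = 0 < D.
3. **Euler update** of Eqs above, concentrations clipped at zero.  An
   undershoot of order `D·M·dt` per step is inherent to consuming the whole
   pool while dilution still removes some of it; larger undershoots are
   logged.

Steady state is declared when the standard deviation of every present
strain's growth rate over 50 consecutive steps falls below `1e-5`
(checked after the last strain introduction); simulations stop at 1000 h
otherwise.  Default protocol: D = 0.2 h⁻¹, 1 mM glucose feed, producer
inoculated at 0.01 gDW/l at t = 0, consumer at 0.001 gDW/l at t = 50 h.

**Discrete-time bias.**  At steady state the availability limit pins a fully
drawn-down resource at `M = M⁰·D·dt/(1+D·dt)` (and a produced one at
`production·dt/(1+D·dt)`) whenever that exceeds the transport-limited level.
The resulting O(D·dt) biases are ~1% for producer biomass and up to ~2% for
consumer biomass at dt = 0.1; the analytical solver reproduces them exactly
when given the simulation's dt.  Transport parameters Vmax and kM shape only
the transient provided ambient concentrations stay small against the feed
scale; for kM approaching 1 mM the dilution loss of the intermediate pool
becomes a real (not numerical) effect of order tens of percent on consumer
biomass.

## Analytical steady states

Because each strain's FBA growth response is monotone in its limiting
resource, the chemostat fixed point needs no damped iteration: bisection on
`μ_P(M₁) = D` pins the primary concentration, bisection on `μ_C(M₁, M₂) = D`
pins the secondary, and the two linear resource balances give the biomasses.
Outcomes partition the (p, c) plane into coexistence, producer-only,
consumer-only (the consumer reaches μ ≥ D on the primary alone and excludes
the producer, which pays for excretion) and washout; the boundary μ = D
counts as persisting.  The solver and the dynamic simulation agree to ≤ 1%
on all coexistence fixtures, and to ≤ 0.1% on the analytic toy system.

## Random viable networks

Networks are presence/absence bit-vectors over a pan-reaction universe
(serialized as one line of 0/1 characters plus a sidecar reaction index).
Sampling starts from a seed containing every FBA-active reaction on the
viability medium plus a uniform random fill to the target size, then applies
**reaction swaps**: delete one random non-protected, non-boundary present
reaction, add one random absent reaction, accept iff the network stays
viable (biomass > ε) on glucose.  Size is conserved either way; boundary
reactions and the recomputed single-deletion essential set are never
swapped.  Each walk ends after a fixed number of *accepted* swaps; per-walk
RNG streams derive from `(seed, walk index)`, so walks are reproducible and
parallelizable.  For sampled networks only viability/producibility verdicts
are reported — never quantitative fluxes, which spurious
thermodynamically-infeasible cycles could distort.  The genome-scale
protocol (networks of 2583 reactions, 500 walks × 5000 accepted swaps — the
reaction count follows the methods-level figure; a conflicting in-text 2251
appears once and is treated as a typo) is exposed through the same entry
point and documented in `examples/sample_random_networks.py`.

## Synthetic fixtures and what they show

* **Toy universes** — random sparse stoichiometries (coefficients in {1, 2})
  over a handful of nutrients with an ATP-like viability currency; the
  generator retries until the universe is viable on its designated primary
  and admits a producible secondary.  Every verdict is recomputable by an
  independent `scipy.optimize.linprog` oracle on the raw matrix, keeping the
  GLPK-backed implementation and its checks on separate code paths.
* **Monod model** — one substrate, biomass yield Y, growth capped at μmax;
  with `Vmax = μmax/Y` the dFBA chemostat follows the Monod law exactly and
  the steady state has the textbook closed form `S* = kM·D/(μmax−D)`,
  `X* = Y(S⁰−S*)`.
* **Cross-feeding fixture** — six metabolites, an efficient growth route, a
  pure-overflow by-product route and a by-product consumption route, chosen
  so that yields (α_S = 0.2, α_B = 0.05), p_max = 2·u_lim − 10D, the cost
  (0.1 h⁻¹ per unit flux) and the full steady-state map are hand-derivable.

These fixtures exercise every pipeline stage without downloads, but they are
deliberately tiny and non-degenerate: passing tests demonstrates the
correctness of the algorithms and bookkeeping, not the biological fidelity
of any genome-scale reconstruction.  Genome-scale behaviour is checked
against the bundled iJO1366 model (counts of primary/secondary sources,
blocked reactions, and the glucose–acetate niche descriptors); the
full pair enumeration is an hour-scale batch and lives in
`examples/full_enumeration.py` rather than the default test run, whose
problem sizes (toy universes of ~20 reactions, 20 walks × 200 swaps,
single-pair genome-scale chemostat runs) keep the suite to a few minutes.

## Numerical choices

* Viability/production threshold ε = 1e-5 flux units, applied uniformly.
* Blocked reactions: flux-variability analysis with all boundary reactions
  opened to ±1000 and a 1e-6 zero cutoff; equals the per-reaction two-LP
  oracle on all synthetic fixtures.  Published genome-scale counts are
  solver- and tolerance-sensitive at the level of a few reactions.
* Bisections: 200 iterations, relative tolerance 1e-10; monotone responses
  make bracketing safe.  Ties at μ = D count as persisting.
* No randomness outside `netsampler`/`synthetic_data`; all RNG flows from
  explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

* The chemostat data model supports N strains, but tests and analytics cover
  producer/consumer pairs; no spatial structure, batch or fed-batch modes.
* Gene–protein–reaction rules, knockouts and thermodynamic loop-law
  corrections are out of scope; by-products other than the designated
  secondary (e.g. CO₂) are tracked but not fed back as carbon sources.
* A strain forced to *consume* (rather than produce) at a floor bypasses the
  availability accounting and is not a supported simulation phenotype; the
  cap-vs-forced-consumption equivalence is verified through the steady-state
  trade-off identity instead.
* The 0.78 gDW/l community-biomass figure often quoted for a 1 mM glucose
  feed is not reproducible under elemental mass balance (1 mM glucose is
  0.18 g/l of substrate); this package's consistent value under those
  conditions is ≈ 0.09 gDW/l, with the dynamic and analytical routes
  agreeing.
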