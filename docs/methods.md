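# Methods

## Modelling framework

All analyses operate on a compartmentalised stoichiometric model: a matrix
**S** (rows = metabolites, columns = reactions, `S[i, j]` the coefficient of
metabolite *i* in reaction *j*), flux bounds, and a linear objective.  The
steady-state assumption of flux balance analysis (FBA), **S·v = 0**, states
that internal concentrations do not change over time.  Fluxes are in
mmol·gDW⁻¹·day⁻¹; biomass fluxes are growth rates in g·gDW⁻¹·day⁻¹.
Substrates carry negative coefficients; exchange reactions are written as
`species → ∅`, so uptake is a negative flux.

FBA optima are unique in value but generally not in flux distribution.
Whenever a *specific* distribution is reported (all scan tables), the
quadratic flux minimisation **min Σᵢ vᵢ²** is solved subject to steady
state, bounds, and the scan's fixed target fluxes (growth rate, nutrient
uptakes, bacteroid oxygen).  The objective is strictly convex, so the
optimum is the unique projection of the origin onto the feasible polytope;
it is interpreted as maximally efficient enzyme usage.  Fixed targets are
imposed as equalities, not lower bounds.

## Solvers and numerics

* **LP** — `scipy.optimize.linprog` (HiGHS), feasibility/optimality
  tolerances 1e-9.  Used for FBA, FVA, consistency checking, the FASTCORE
  LPs and all oracle computations.
* **QP** — OSQP with `eps_abs = eps_rel = 1e-10` and solution polishing
  (an exact active-set refinement of the ADMM iterate).  A plain LP
  feasibility probe runs first because ADMM is slow to *certify*
  infeasibility for points just outside the feasible set (e.g. oxygen
  values just below the minimum requirement).  Fully deterministic: fixed
  variable ordering, no randomisation anywhere in the engine; repeated
  solves agree to better than 1e-9 per flux.
* A second, algorithmically independent QP route is kept in
  `solve.min_norm_qp_nullspace`: null-space elimination of the equality
  constraints followed by the Lawson–Hanson least-distance transformation
  to NNLS.  Tests use it (together with an LP-based KKT certificate:
  no feasible direction `d` with `S·d = 0` and `2v·d < 0` exists at the
  reported optimum) to cross-check the production solver.  One caveat
  discovered during development and worth recording: when a variable is
  pinned by *equal lower and upper bounds* and those are encoded as an
  opposing inequality pair, the least-distance geometry becomes degenerate
  (multipliers of order 1e15) and the transformation returns certified-
  looking but wrong optima.  The reference implementation therefore folds
  every `lb == ub` variable into the equality system before reducing.
* Tolerances: mass/charge balance 1e-6 on element and charge deltas
  (stoichiometries may be real-valued, e.g. biomass); flux-consistency
  threshold eps = 1e-4 (the customary FASTCORE activation level);
  essentiality threshold 1e-6 absolute on the objective, with borderline
  cases (within 10×) reported separately; steady-state residual of any
  optimal solution ≤ 1e-6 by construction and asserted in tests.

## Consistency analysis and FASTCORE

`find_blocked_reactions` implements the FASTCC scheme: one support-
maximisation LP (LP7) over all irreversible reactions, then directional
probing of the remaining candidates with sign flips, falling back to
single-reaction maximisation.  The complement of the blocked set is the
flux-consistent part.  The per-reaction two-LP brute force is retained in
the test suite as an independent oracle, never as the implementation.

`fastcore_extract` follows the original algorithm: alternate a support-
maximisation LP over the not-yet-activated core with an L1 flux-magnitude
minimisation over the non-core penalty set (LP10), flipping the sign of
reversible candidates when a direction fails.  Reversible reactions are
handled by this flipping scheme (the original formulation) rather than by
splitting into irreversible column pairs; the two are equivalent in what
they certify, and flipping keeps the LPs half the size.  LP10 scales all
bounds by 1e5 so that reactions stoichiometrically coupled to a forced
core flux (e.g. a carboxylation running at 1/6 of its partner) stay above
the support threshold — without the scaling the output can contain blocked
leftovers.  Ties in the support LP are broken deterministically by
reaction-id order.  The output contains the whole core, is flux-
consistent at eps, and is *near*-minimal, which is the algorithm's
contract; tests assert size ≤ exhaustive minimum + 2 on toy networks.

Expression scoring maps a GPR rule to a reaction activity with OR→max
(isozymes) and AND→min (complex subunits); a reaction enters the tissue
core iff its score reaches the user-supplied threshold (there is no
universal default; the bundled fixtures use 1.0 against expression values
of 0/10).  Reactions without a GPR are never expression-selected but may
be pulled in as support.  Boundary reactions (exchanges, maintenance) and
biomass are protected — always added to the core — with a per-tissue
protection list, because tissue boundaries genuinely differ (a root has
no photon exchange).

## Model composition

Tissue replication duplicates every compartment, metabolite and reaction
under a tissue prefix; inter-tissue transporters are explicit 1:1
transport reactions; the combined biomass consumes α units of shoot and
1−α units of root biomass per unit growth (tissue biomass reactions are
rewired to produce a pseudo-species; they remain in the model but the
objective references only the combined reaction).  α defaults to 0.67 in
the CLI (shoot-dominated biomass allocation); the bundled fixtures pin
α = 0.5 so that symmetric tests have exact expectations.

The bacteroid attaches to the root as a non-growing flux subsystem
(differentiated bacteroids have no growth requirement; their product is
fixed nitrogen).  Its bounds are scaled by the symbiont mass fraction
f (default 0.02 gDW symbiont per gDW plant) so all its fluxes read per
gram plant; its maintenance ATP demand (default 30 mmol·gDW(sym)⁻¹·day⁻¹,
i.e. 0.6 per gram plant) becomes a fixed lower bound.  Coupling follows
the literature picture: malate, succinate, glutamate and oxygen flow
plant→bacteroid; alanine and ammonia (arriving protonated as ammonium,
with one plant-side proton in the transport stoichiometry) return.
Oxygen carries the sole active cap (default 5 mmol·gDW⁻¹·day⁻¹); every
other coupling bound is configurable.

## The synthetic fixtures

The mini-plant (57 reactions, 55 metabolites, compartments external/
cytosol/plastid/mitochondrion) emulates the structure of a genome-scale
plant reconstruction at toy scale: lumped light reactions and
photophosphorylation, a lumped Calvin cycle producing hexose phosphate,
starch synthesis/degradation with maltose export through the plastid
envelope, glycolysis, TCA, oxidative phosphorylation at a configurable
P/O ratio, nitrate reduction at the canonical 8 e⁻ per nitrogen,
ammonium assimilation (GS/GOGAT, glutamine synthetase, glutamate
dehydrogenase, alanine transaminase), sucrose cycling, carbonic
anhydrase with proton/bicarbonate exchanges, dicarboxylate exudation,
biomass and ATP maintenance.  Every internal, transport and maintenance
reaction is balanced for C, H, N, O, P and charge; protons are ordinary
compartment-specific species (formula H, charge +1) with no implicit
balancing, which is what makes the trans-membrane charge bookkeeping of
the nitrogen scans meaningful.  The biomass drain consumes only neutral
species (glucose, alanine, glutamine) plus an internally balanced ATP
hydrolysis, so growth itself is charge- and free-proton-neutral.

The mini-bacteroid (23 reactions) carries nitrogenase at the classical
stoichiometry N₂ + 8 H⁺ + 8 e⁻ + 16 ATP → 2 NH₃ + H₂ (8 electrons is the
only count that closes the hydrogen/charge books with one H₂ per N₂; the
ATP cost is configurable), malate and succinate TCA entry points that
differ by exactly one reductant, a reversible pyruvate carboxylase,
alanine dehydrogenase, glutamate–pyruvate transaminase, 2-oxoglutarate
oxidation with the succinyl-CoA-synthase ATP yield, and oxygen-capped
oxidative phosphorylation.

Default parameters, chosen once: P/O ratio 2.5 (fixture behaviour is
asserted robust over [1.5, 3]); photon cap 100 mmol·gDW⁻¹·day⁻¹ (makes
daytime growth light-limited); plant maintenance 1 mmol ATP·gDW⁻¹·day⁻¹;
biomass per gram: 0.25 glucose, 0.10 alanine, 0.025 glutamine, 6 ATP
(nitrogen demand 0.15 mmol·g⁻¹).  Both fixtures self-check at build time:
zero internal imbalances and a zero optimum for the closed-exchange
energy-cycle certification (directionalities were chosen to exclude
thermodynamically infeasible cycles; the certification maximises the
maintenance demand with all exchanges closed and forced demands relaxed).

The random-network generator produces single-compartment models from
balanced templates only (equal-carbon conversions and carbon-summing
merges), with backbone exchanges guaranteeing that at least 80 % of
reactions are flux-consistent and a ~10 % quota of deliberate dead ends
providing blocked reactions for the oracle tests.  Reproducible from the
seed.

What the fixtures do *not* capture: genome scale (2900+ reactions),
secondary metabolism, isozyme redundancy, kinetic and regulatory
constraints, and sub-cellular proton-motive coupling beyond explicit
stoichiometry.  Passing fixture tests therefore demonstrates that the
*methods* behave correctly and that the qualitative physiology is a
structural consequence of the stoichiometry — not that the numeric values
match any real organism.

## Scan design

* **Nitrogen sources.** At each ammonium fraction λ (default 21 even
  points), ammonium uptake is fixed to λ·total and nitrate to
  (1−λ)·total, growth to 0.1 g·gDW⁻¹·day⁻¹, under the night regime; the
  fixture's total nitrogen equals the biomass demand at that growth.
  Reported markers: starch exchange, TCA, mitochondrial ATP synthase,
  proton and bicarbonate exchanges.  One bookkeeping subtlety: a strictly
  convex flux minimum spreads any export over all parallel routes, so the
  fixture carries a uniform H⁺/HCO₃⁻ co-export background (chemically an
  H₂CO₃ export, i.e. CO₂ leaving partly as bicarbonate).  The acid-base
  signal of the nitrogen source is therefore read from the **net acid
  export**, H⁺ export − HCO₃⁻ export, which charge conservation ties
  exactly to the signed charge of the nitrogen uptake: positive on pure
  ammonium (soil acidification), negative with bicarbonate release on
  pure nitrate, zero at equimolar supply.
* **Symbiosis comparison.** Plain FBA growth maximisation per external
  ammonium level, for the plant with and without the attached bacteroid,
  under the day regime with nitrate closed.
* **Oxygen availability.** The maximal growth rate is computed once on
  the wild-type symbiotic model; growth is then fixed at 80 % of it (also
  for knockout variants, which are held to the same demand).  Bacteroid
  oxygen uptake is fixed per grid point; the default grid spans 0 → 2×
  the wild-type minimum feasible oxygen.  Because the attainable oxygen
  set at fixed growth is the projection of a polytope — an interval — the
  minimum is obtained exactly by a single LP rather than by bisection.
  Infeasible points are flagged and the scan continues.
* **Carbon conversion.** Growth is fixed, maintenance demands are
  excluded (the quantity is the *theoretical maximum* conversion,
  considering only the energy and redox requirements of biomass
  formation), the starch import is minimised by LP, and the unique QP
  vector at that minimum verifies carbon-atom closure (imported carbon =
  biomass carbon + exported carbon, within 1e-6, from elemental
  formulas).  Efficiency is biomass carbon over imported carbon; the
  respired fraction is its complement.  Ammonium always beats nitrate on
  any network where nitrate reduction consumes reductant.

## Knockouts and essentiality

Knockouts are reaction-wise (GPR rules are carried but not used for
deletion): bounds forced to (0, 0), the objective re-maximised.  A
reaction is essential when the knockout optimum falls below 1e-6 or the
problem becomes infeasible.  Note that zeroing a reaction is only a
*restriction* when zero was admissible: knocking out a maintenance
demand with a positive lower bound relaxes the model and can raise the
optimum — the monotonicity property (knockout ≤ wild type) is asserted
for zero-admitting reactions.

## Known limitations

* The QP engine targets the bundled fixture scale (≲ a few hundred
  reactions per solve); genome-scale quadratic minimisation would want a
  sparse factorisation backend.
* Strictly convex flux minimisation spreads flux over parallel routes;
  single-route statements ("only carrier X") hold exactly only where a
  binding constraint (e.g. reductant disposal at minimal oxygen) pins the
  alternatives to zero, and otherwise as dominance statements.
* Loopless-FBA MILP formulations, thermodynamic constraints and
  gene-level deletions are out of scope by design.
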