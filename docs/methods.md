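# Model and methods

`microstoich` is an individual-based, spatially explicit simulator of
carbon and nitrogen flow through a decomposing piece of leaf litter. This
note describes the model, the choices behind every tunable parameter, what
the calibrated defaults do and do not emulate, and the numerical
conventions the implementation commits to.

## The model in brief

The world is a square lattice of *microsites* (default 100 × 100; each site
conceptually a 10 µm cube, the grid a 1 mm² patch of litter). A microsite
holds

* three complex substrate pools, each an explicit (C, N) pair: native
  **plant material** (C:N set by the scenario's litter stoichiometry),
  **C-rich microbial remains** (MR-C: cell walls, lipids, storage
  compounds; C:N 150) and **N-rich microbial remains** (MR-N: proteins,
  nucleic acids and denatured extracellular enzymes; C:N 5);
* dissolved organic matter (**DOM**, the only pool microbes can take up)
  and dissolved inorganic nitrogen (**DIN**);
* three extracellular enzyme pools, one per complex substrate;
* at most one small colony of microbial cells, all belonging to one
  *functional group*.

A functional group is an immutable trait bundle: macromolecular composition
(fractions of cell C in soluble / C-rich / N-rich components, which fix the
whole-cell C:N as `1 / (f_dom/15 + f_mrc/150 + f_mrn/5)`), maximum cell
size MCS (division threshold, fmol C), colony capacity per site, enzyme
investment (fraction of post-maintenance uptake C) and the allocation of
that investment across the three enzyme classes. Small MCS implies fast
surface-limited growth *and* high stochastic mortality (r-strategist);
large MCS the opposite (K-strategist).

One time step represents 3 h and proceeds as:

1. **Enzymatic degradation** per site: Michaelis–Menten flux
   `vmax_i · E_i · S_i/(km_i + S_i)` per class, capped at the pool, products
   entering the site's DOM at the source pool's C:N.
2. **Cell physiology** per cell: surface-limited DOM uptake
   (`uptake_coeff · B^(2/3)`, colony members sharing the site DOM in
   proportion to capacity; cells at MCS are satiated and take nothing until
   they divide), then a strict sequential budget — maintenance respiration,
   constitutive enzyme production (one tenth of maximal production,
   sustained from biomass under starvation), regular enzyme production,
   growth — followed by stoichiometric balancing: cell C:N is fixed, so
   excess N is mineralised to DIN and, under N limitation, surplus C is
   respired as overflow. Growth N is drawn from uptake N first, then from
   site DIN (immobilisation).
3. **Enzyme aging**: a fraction `1/enzyme_lifetime` of each enzyme pool
   denatures into MR-N each step (memoryless decay; the mean lifetime
   equals the configured value).
4. **Demography**, grid-synchronous: starvation death below
   `starvation_min · MCS`; catastrophic death with probability
   `mortality_ref · mcs_ref / MCS` (inverse-MCS scaling, exponent 1); dead
   cells partitioned into DOM / MR-C / MR-N by their macromolecular
   composition; division at MCS with the daughter filling a free colony
   slot, else an empty Moore neighbour, else invading an occupied neighbour
   with probability 0.01 (residents die to necromass); a fully blocked
   division is deferred, the excess above MCS respired as overflow.
5. **Transport**, grid-synchronous: DOM (C and N together) and DIN exchange
   `diff/4` of each site's content with each von-Neumann neighbour on a
   torus; a fraction `leach_fract` of everything in transit is lost and
   ledgered as leached.

Whole-grid ledgers track cumulative DOC uptake (U_DOC), respiration by
pathway (maintenance, growth overhead, enzyme overhead, overflow), enzyme C
produced (P_ENZ), leached C and N, and N mineralised/immobilised. Carbon
and nitrogen closure against the initial stocks is asserted to 1e-9
relative whenever auditing is enabled, and holds at every step of the test
scenarios.

### Respiration conventions

Maintenance is `maintenance_fract · biomass` per step (C only). Enzyme
production of E fmol C costs `E · (1 + resp_enz)`. Of the C funnelled into
growth, a fraction `resp_growth` is respired, i.e. growth equals
`(1 − resp_growth)` of the C consumed by the growth process; cell-level CUE
is therefore bounded by
`(1 − resp_growth) · (1 − enz_fract · (1 + resp_enz))`.

### Enzyme nitrogen

Enzymes are protein and carry C:N = 5 (`enzyme_cn`). Production consumes N
(uptake N first, then — for starving cells — N freed by biomass shrinkage,
then DIN; production scales down if N still falls short). A starving cell
funds its constitutive production entirely from biomass: because biomass
carries less N per C than protein, it shrinks a little more than the C cost
alone and respires the surplus, so constitutive production never vanishes.
Denatured enzymes carry their N into MR-N, which is what keeps that pool
protein-like. This choice closes the N books exactly, and it has a visible
systemic consequence: a steady ~12% of all C uptake cycles through the
enzyme pool into MR-N at C:N 5, making enzyme turnover a major internal N
recycling flux.

## Community carbon use efficiency

CCUE is computed **per time step** from the step's ledger increments,

    CCUE = (U_DOC − R − P_ENZ) / U_DOC,

the fraction of that step's community C uptake that became growth. The
cumulative series (same formula on the whole-run ledgers) is recorded
alongside. The two differ systematically: the cumulative ratio is dominated
by the N-limited bulk phase of decay, while the per-step series rises late
in decay as the community shifts onto recycled, N-rich necromass. The
"late-decay CCUE" reported by the analysis tools is the same formula
applied to the ledger increments over the last 20% of steps (equivalently,
the flux-weighted mean of the per-step series over that window, which
keeps famine steps with negligible uptake from dominating the estimate).
When a window has no uptake the value is recorded as missing, never as
zero.

## Threshold element ratio theory

The classical mass-balance threshold (the litter C:N above which
decomposition is N-limited) is implemented as `TER = B_CN · NUE / CUE`,
with the N-reuse generalisation `TER_r = r · B_CN · NUE / CUE` where `r` is
how many times more often the average N unit is reused per unit time than
the average C unit (`r = 1` recovers the classical form). At NUE = 1 and
CUE = 0.5 the biomass C:N range 8–15 maps to TER 16–30. These closed forms
are the foil the simulator's emergent behaviour is contrasted against: in
the simulation, community-driven necromass recycling effectively raises `r`
with litter C:N instead of depressing CUE.

## Parameters: defaults and rationale

All defaults live in `src/microstoich/data/default_params.yaml` (the single
version-controlled source; the dataclass mirrors it). Structural constants
— grid 100 × 100, 3-h step, invasion probability 0.01, constitutive
fraction 0.1, component C:N 15/150/5 — are fixed by the model design and
the loader refuses to change them without an explicit override flag.

Every rate constant is a calibration decision of this implementation; the
YAML documents a plausible range next to each. The defaults were fixed in
one calibration pass, guided by three structural considerations and the
qualitative behaviour of the emergent observables, and not revisited
afterwards:

* **Loop gain.** A producer's enzymatic supply loop has gain
  `vmax · sat · enz_fract · enzyme_lifetime` (sat = substrate saturation).
  The plant-class gain must exceed 1 for a population investing 12% with
  70–90% plant allocation to persist, but only barely — surplus DOM beyond
  the producers' own uptake capacity leaks to non-producing neighbours, and
  too much of it lets opportunists and other cheats swamp the enzyme
  producers. `vmax = (0.55, 2.0, 1.5)` with lifetime 20 puts plant
  degraders (90% allocation) at gain ≈ 1.2 and the uniform population (70%)
  just below 1, where it is carried by the necromass side-loops.
* **Late-decay viability.** Small `km` (10 fmol per site) keeps the
  saturation factor high as pools run down, so the community can actually
  reach 90% mass loss rather than stalling when the loop gain decays below
  1; strong MR-C and MR-N turnover lets the remains degraders finish the
  necromass in the second successional phase.
* **Slow necromass supply.** Low catastrophic mortality (0.001 per step at
  MCS 100, i.e. ~125-day expected lifespan; ten-fold higher for MCS-10
  cells) delays the build-up of microbial remains, which is what gives
  plant degraders their long head start at low litter C:N. Lean maintenance
  (0.0017 per step) and a low starvation floor (5% of MCS) let colonies
  ride out local famines instead of collapsing into boom–bust cycles whose
  necromass pulses would feed the remains degraders prematurely.

Initial-state parameters the source model leaves open (per-site plant C
3000 fmol, initial DOM 5 fmol C at C:N 15, DIN 1 fmol N, active enzymes
0.3 fmol C, 5% of sites seeded per group with one founder cell at MCS/2 —
the post-division size, placing founders mid-cycle) are free scenario
choices: small enough not to distort the competition, large enough to carry
every scenario through establishment. With these defaults the one-group
control at litter C:N 50 on a 50 × 50 grid loses ~60% of its mass in
roughly 40 simulated weeks and reaches 90% in ~60 weeks.

## What the scenarios emulate

* **Two-group life-history sweep**: a fixed slow, high-C:N reference group
  against a second group varying cell C:N class (6/9/12), MCS (100/10) and
  enzyme investment (12%/6%), litter C:N 15–95, five seeds — the
  competition experiment relating life-history traits to litter
  stoichiometry.
* **Three-group substrate-specialist model**: plant degraders (enzyme split
  90/0/10), microbial-remains degraders (0/50/50) and enzymatically silent
  fast-growing opportunists, at litter C:N 45–75 until 90% mass loss. This
  is the configuration in which community-level stoichiometric regulation
  emerges: DOM C:N converges to a common low value across litter
  stoichiometries and late-decay CCUE stabilises.
* **Uniform-population control**: one group, all enzyme classes
  (0.7/0.15/0.15). Its DOM C:N stays positively coupled to litter C:N —
  the contrast that isolates the effect of substrate-specific functional
  diversity.

The analysis scale for the emergent evaluation is a 50 × 50 grid with four
replicate seeds per condition; the per-site dynamics are scale-free, and at
this size the grid aggregates are stable enough that replicate spread, not
grid size, dominates the uncertainty.

## What the generator does *not* emulate

No phosphorus or micronutrients; no temperature, moisture or pH
dependence; no fungal hyphal translocation, antibiotics or other
interference competition; no enzyme diffusion (only DOM and DIN move); no
variable cellular stoichiometry, storage compounds or dormancy. Litter is
chemically uniform at t = 0. Passing tests therefore say nothing about
field litter with leachable solubles, successive cohorts of litter input,
or taxa whose stoichiometry drifts with growth rate.

## Numerical conventions and degenerate inputs

* Forward-Euler per 3-h step everywhere; degradation and uptake fluxes are
  capped at the available pool, so pools cannot go negative (asserted).
* The per-site phase (degradation → uptake/budget → enzyme aging) touches
  only site-local state, so the vectorised whole-grid evaluation is exactly
  equivalent to visiting sites in any order; the random site permutation
  is still drawn every step so that the documented RNG consumption order
  (permutation → mortality draws → division order → colonisation/invasion
  draws) is stable. One PCG64 stream per run; a fixed seed gives a
  bit-identical trajectory.
* Division conflicts are resolved sequentially in a random order; an
  invasion victim's biomass is partitioned to necromass at the victim's
  composition.
* Zero denominators (empty DOM, zero uptake) produce missing values in
  observables, never zeros; `enzyme_lifetime = inf` disables enzyme aging;
  `mass_loss_stop = 0` returns the initial record immediately.
* Mass-loss fraction is `1 − (on-grid C)/(initial C)`, so both respiration
  and leaching count as loss. The time of 50% loss is interpolated
  linearly between recorded steps. The decay constant `k` is a
  least-squares fit of log remaining C over the 0–60% mass-loss window
  (configurable).

## Known limitations

* The emergent targets (DOM C:N convergence, late CCUE, biomass ratios at
  50% loss) are sensitive to the calibration; the defaults are one
  self-consistent point, not a fitted optimum. In particular the
  plant-to-remains degrader biomass ratio at litter C:N 75 tends to sit
  somewhat above the narrow historical value, and the one-group control's
  late DOM C:N at litter 75 somewhat below it: with protein-C:N enzymes,
  enzyme turnover pins late DOM C:N near the low twenties, and pushing it
  higher destabilises the uniform population. See the acceptance outputs
  for the currently measured values.
* Runs slightly beyond ~90% mass loss enter a regime where the surviving
  population is small and observables get noisy; analyses should not read
  much into the post-stop tail.
* The scheduler's synchronous demography/transport phase is a design
  choice; a fully random per-site interleaving is isolated behind
  `run_step` and could change fine-scale colonisation statistics.
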