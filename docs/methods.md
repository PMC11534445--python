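# Methods

## Model structure and assumptions

`scavsim` integrates a five-state consumer–resource system: a single
shared vegetation pool (logistic regrowth, rate `R0 = 4 yr⁻¹`, carrying
capacity `k0 = 10 ton ha⁻¹`), two hunted ungulate guilds (deer, boar), an
aggregated facultative-scavenger guild, and the wolf. All biomasses are
densities in ton ha⁻¹; time is in years. The structural assumptions are
deliberate simplifications: one vegetation resource shared by deer, boar
and scavengers (so competition is direct and complete); wolves eat only
live deer and boar (no wolf scavenging, no livestock or alternative
resources); no scavenging of wolf carrion; no boar cannibalism; no space,
seasons, age structure or demographic stochasticity. Populations are
food-limited only.

Carrion is bookkept as an instantaneous **flux** (ton ha⁻¹ yr⁻¹), never a
standing stock. At each instant the deer carrion pool collects natural
mortality, the leftover fraction `L_D` of the hunting flux and the
unconsumed fraction `v` of wolf kills; boar analogously. Boar scavenge
deer carcasses before anyone else: a saturating response of the
per-capita carrion supply sets the realized carrion diet portion
`ü < u = 0.2`, the boar's total intake capacity shrinks as its diet
shifts toward carrion (carrion converts at `C_DB = 0.069` versus
`C_VB = 0.055` for vegetation, so a carrion-rich diet needs less mass for
the same growth), and only the residual deer carrion plus the boar
carrion pool is available to the scavenger guild. Scavenger carrion
uptake is linear in demand but capped at availability (Holling type I on
top of a type-II intake capacity).

## Parameters

Defaults are the calibrated values of the source web: the three
parameters revised during calibration are `C_VD = 0.025`, `C_XS = 0.1`
and `M_W = 0.2 yr⁻¹`; all others keep their literature-derived initial
values. Intake and predation rates derive from individual life histories
via `derive_rate_from_life_history` (annual food requirement ÷ mean
weight, inflated by 1/(1−v) where part of the kill is unconsumed):
986/42 ≈ 23.5 yr⁻¹ (deer), 1209/60 = 20.15 yr⁻¹ (boar),
1642.5/25/0.68 ≈ 96.6 yr⁻¹ (wolf). Hunting-regime parameters
(`T`, `H`, `L`, each policy-bounded to [0, 1]) are scenario variables,
not biology; `ParameterSet` carries medium-policy defaults
(`T = L = 0.5`, `H = 1`) that scenarios override.

Two renderings of the scavenger carrion cap are exposed via
`ParameterSet.carrion_dialect`. The default `"literal"` caps total demand
`Ä_XS·S` at each pool separately, exactly as the min-form of the growth
equations reads. The `"proportional"` dialect first apportions demand to
each pool by its share of the total resource, mirroring how vegetation
consumption is apportioned; it is strictly more conservative. The literal
form is the default because it is the printed form; the choice only
matters when scavenger demand exceeds carrion supply.

## Numerics

Integration uses SciPy's LSODA (stiffness-switching Adams/BDF) at
`rtol = 1e-8`, `atol = 1e-10`, over a 250-year horizon with a 1-year
output grid. The tolerances are this package's choice, validated by two
properties: the vegetation-only run tracks the closed-form logistic
solution to < 1e-6 everywhere, and halving both tolerances changes no
output state by more than 1e-5 relative on the default scenario.

Biomasses are physically non-negative, and the implementation enforces
this at three layers: the right-hand side clamps each component at 0
before evaluation; integration proceeds one output interval at a time;
and between intervals any component below the extinction floor
(`1e-12 ton ha⁻¹`) is snapped to exactly 0. The segmented floor is
load-bearing, not cosmetic: in a single-call integration, multistep
round-off on the order of `atol` can seed a structurally absent guild
(initial biomass exactly 0) with ~1e-12 of biomass, which then grows back
to order 1 — a qualitatively wrong outcome. Snapping between intervals
makes extinction absorbing, matching `rhs(0) = 0`.

Degenerate points are defined by their limits: the boar carrion portion
is 0 when boar or deer carrion are absent; the squared prey-preference
shares `X²/(D²+B²)` are 0 when both prey are extinct; vegetation
consumption by scavengers is 0 when the total resource is 0.

## Scenarios and experiment design

The default factorial grid crosses the four presence combinations (boar
and wolf present/absent) with hunting targets {0, 0.5, 1.0} ton ha⁻¹ and
leftover fractions {0, 0.5, 1.0}, with `T_D = T_B` and `L_D = L_B` varied
jointly and `H = 1 yr⁻¹` — 36 scenarios. The specific medium/high target
values are this package's choice within the studied [0, 1] range, evenly
spaced; the zero-target level reproduces the full-extermination hunting
regime. Default initial biomasses for present guilds are
`V=5, D=0.5, B=0.5, S=0.1, W=0.05 ton ha⁻¹`. An incremental
model-building sequence (V; V+D; V+B; V+D+B; V+D+B+S; full web) supports
step-wise inspection.

Sensitivity analysis is a full factorial of fixed multipliers (default
0.75, 0.875, 1, 1.125, 1.25) applied to chosen parameters, with
fraction-type parameters capped at 1 after scaling, a 10,000-run guard,
and end states summarised by the mean over years 200–250. The 50-year
window absorbs residual oscillation around equilibria. The multistart
check integrates each scenario from the base initial state scaled
component-wise by 0.5×, 1× and 2× — deterministic multipliers, no RNG
anywhere in the pipeline — and reports the maximum relative spread of
window means across starts, over states whose mean biomass exceeds
1e-6 ton ha⁻¹ (states extinct from every start say nothing about the
attractor).

## Known limitations

* **Long transients vs. the 250-year window.** Several grid cells have
  not fully converged by year 250: boar+wolf cells retain weakly damped
  oscillations (1–3% residual multistart spread; all starts agree by
  ~3000 years), boar-without-wolf high-target cells show deer slowly
  collapsing toward exclusion (large *relative* spread on a tiny decaying
  biomass), and in no-boar+wolf high-target cells the wolf equilibrium is
  so marginal (W* ≈ 0.0035 ton ha⁻¹) that a doubled starting state
  crashes it for far longer than the horizon. End-state comparisons at
  250 years therefore depend mildly on the start point in those cells,
  even though the attractor itself does not.
* **Competitive-exclusion sensitivity of `C_VS`.** Because all consumers
  share one vegetation pool, a 30% increase of the vegetation-to-
  scavenger conversion factor can tip the competition against deer in
  wolf-absent cells (deer collapses, scavengers more than double). The
  scavenger response to `C_VS` is strongly regime-dependent rather than
  smoothly bounded; the decrease direction (×0.7) stays within a factor
  0.5–1 across the whole grid.
* The model is theoretical: absolute biomass values have no predictive
  power for any specific ecosystem; patterns and orderings are the
  object of study. No parameter is fitted to field data here.
* The summary transform mapping the carrion-to-vegetation growth ratio
  into [0, 1] is the vegetation share of total scavenger growth; any
  monotone transform preserves the orderings but not pointwise values.
  Time points with zero total scavenger growth report share 1 and are
  flagged.
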