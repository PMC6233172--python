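# Model and methods

This note documents the simulator's assumptions, the synthetic calibration
inputs, the numerical choices made where the design was genuinely open, and
the limits of what desk-scale runs demonstrate.

## Overview of one simulation

1. Generate calibration pools (tolerance limits per guild, trophic
   level/specificity records) and a climate grid.
2. Draw a global species pool; build the 26×26 trait adjacency and calibrate
   its accessibility bounds over random phenotype pairs.
3. Populate localities from random grid cells until the target count is met;
   assemble, prune and weight a food web per locality.
4. Run a preliminary dispersal/colonization phase.
5. Step the climate for `n_steps`; at each step apply (in order) temperature
   change → adaptation → primary extinctions → co-extinction cascades
   (co-extinction scenario) → recruitment → colonization. Record global and
   extremophile richness.

The per-step operation order is a design choice (the underlying procedure is
order-ambiguous): extinctions respond to the step's new climate before any
network repair, so rescue mechanisms act on the post-extinction state.

## Synthetic calibration inputs

The empirical inputs of the original study (occurrence-derived plant
tolerances, lab-derived animal tolerances, a gridded climatology, a pooled
trophic-level list) are replaced by generators that emulate their stated
summary statistics. CSV readers accept user-supplied real equivalents with
the schemas `tolerance(lower_c, upper_c, guild)`,
`trophic(trophic_level, specificity)` and `climate(lat, lon, tmin_c, tmax_c)`.

**Tolerance pools.** Limits are drawn as correlated normals per guild —
plants 1.3 ± 4.7 / 23.7 ± 4.8 °C (lower/upper, median ± 1σ), animals
23.4 ± 12.2 / 35.0 ± 4.8 °C — with correlation +0.8 between a species' two
limits and rejection of inverted pairs. The correlation reflects that
realized thermal niches shift along climate gradients far more than they
stretch; independent draws would hand heat-adapted species implausible cold
hardiness. Because rejection truncates the joint distribution, the location
parameters are pre-calibrated by a fixed-seed fixed-point iteration so pool
medians land on the targets (verified to ±0.5 °C at n ≥ 4000). Endotherms
share the published animal aggregate but get a narrower cold-limit spread
(σ = 6 °C; endothermy buffers cold); at their ~0.1% share of consumers this
leaves the aggregate statistics untouched.

**Trophic pool.** Basal fraction 0.35 (chosen so the ≥20%-basal locality
filter passes without excessive rejection); non-basal levels 1–5 with
geometrically decaying frequency (ratio ½); specificities Beta(1.2, 4)
clipped to (0, 1] — right-skewed, most consumers specialists. The original
pooled empirical distribution is unpublished; this stand-in is the main
unconstrained input.

**Climate grid.** Cells sit on the 1° lattice with latitudes drawn
proportionally to land area per band and three deliberate, Earth-like
features: a hottest-month maximum that stays near 30–33 °C from the equator
through ~40° before dropping steeply poleward; a seasonal range that widens
strongly away from the equator (continental winters), so the coldest-month
minimum falls much faster with latitude than the maximum; and Gaussian noise
(2.5 °C on the maximum, 4 °C on the range) standing in for
maritime/continental variation. The min/max covariance matters: a naive
cosine summer profile creates mild-summer mid-latitude refugia that real
climatologies do not offer, and those refugia qualitatively change the
collapse dynamics.

## Key mechanisms and their numerical choices

**Admission.** A candidate joins a locality when its margin
`Tol_d = min(loc_t − sp_t, sp_T − loc_T)` is non-negative (the plain
"compatibility" reading); a stochastic variant (admission probability
1 − instantaneous extinction probability) is available via
`WorldConfig(threshold_admission=False)`. Localities need ≥5 species and
≥20% basal share, webs must assemble with every species linked and connected
to a basal resource, or the cell is rejected and replaced.

**Integrated extinction risk.** The instantaneous probability
(0 above 5 °C margin, 1 below 0, else `1/(1+Tol_d)`) is averaged over each
population's residence time. The standalone operation reconstructs
temperatures linearly and evaluates 100 quadrature points; the simulation
loop accumulates the same trapezoid at unit-step resolution over the realized
trajectory (equivalent for linear change, exact for the realized noise).
Per-step removals use the conditional hazard
`h_k = (P_k − P_{k−1}) / (1 − P_{k−1})` with `P_k` the running maximum of the
integrated probability, so `P` acts as the cumulative extinction CDF and
exposure is never double-counted; populations whose margin turns negative are
removed outright.

**Cascades.** A consumer dies when the lost fraction of its initial resource
stock (link-weight sum at web construction, or at establishment for
colonizers) is strictly positive (ε = 1e-12 guards float noise) and ≥ the
threshold θ; θ = 0 therefore kills on any loss and θ = 1 only on complete
depletion, and a consumer at exactly zero stock always dies. Freed weight is
redistributed within a cascade generation, scaled by the reallocation ratio,
proportionally to current use. Evaluation within a generation is batch
(simultaneous), making the result order-independent; iteration stops at a
fixpoint. Basal species are never cascade victims. Note a non-obvious
consequence verified by property testing: with reallocation active, a *lower*
threshold does not always produce a superset of extinctions — an early death
can free weight that rescues a third party — so threshold monotonicity is
only guaranteed at ratio 0.

**Colonization.** Dispersal succeeds with probability 1/d (degree-space
Euclidean distance, clamped ≥ 1 cell; no longitude wraparound — a documented
simplification). Invasion susceptibility is the target web's connectance
(co-extinction scenario) or the initial-to-current diversity ratio clamped to
1 (tolerance scenario). Tolerance-scenario competition engages each same-level
resident with probability equal to phenotype similarity `2M/T`; the colonizer
must match or beat every engaged resident's margin (ties favour the
colonizer) and displaces them all, or — if none engage — establishes with
probability equal to climatic suitability. In the co-extinction scenario the
colonizer takes over same-level consumers' links (margin comparison plus an
accessibility coin per link, weights inherited), may enrol as an additional
resource (taking a uniform random fraction of an existing link's weight, the
original link decremented by the same amount so recruitment can later repair
it), and basal colonizers replace basal resources in links without
outcompeting the residents. A migrant whose species is already resident in
the target fails. Residents stripped of their last link die, with cascades.

**Recruitment.** Each (target, source) locality pair fires per step with
probability 0.01; links whose resource survives in the source regain
1/d × initial weight, capped at the initial weight.

**Adaptation.** Each population independently, with a per-simulation
probability in [0, 1e-4], extends the trajectory-facing limit by
N(0.75, 0.25) °C.

**Paired randomness.** Climate increments, adaptation draws and extinction
hazards are generated by a counter-based hash keyed on
(seed, purpose, step, locality, species), so paired scenario runs expose
every shared population to identical draws; with migration disabled the
co-extinction richness is then dominated by the tolerance richness at every
step, as asserted in the tests. Colonization and recruitment use ordinary
per-scenario generators.

## Scales, defaults and runtime

Full-scale defaults follow the study conditions: 100 000-species pool with
100 extremophiles, 100–500 localities, 100–1000 candidates per locality,
5000 steps, 10³–10⁵ preliminary colonization events, 10⁶ calibration pairs
for the trait matrix. `SimulationConfig.desk_scale()` is the reduced
configuration used by the tests and the acceptance script: 2000 species,
4 extremophiles (≈ the full-scale share), 20–50 localities, 1000–5000
preliminary events, 2×10⁵ calibration pairs, full 5000 steps. A paired
desk-scale run takes ~5 s; the 2×50-replicate acceptance experiment ~7 min
on one CPU.

## What desk-scale runs do and do not show

The qualitative results are robust at desk scale: co-extinctions collapse
global diversity within a few °C of change (in line with the ~5–6 °C figure
the original analysis reports and cross-checks against the end-Permian and
Chicxulub events); extremophiles die with their webs, far from their own
limits; heating disassembly is harsher than cooling; and the robustness
underestimation from ignoring co-extinctions is large, with heating >
cooling.

The *medians* of the underestimation statistic land at roughly half to a
quarter of the full-scale values. The statistic is a ratio of areas whose
numerator (tolerance-only survival) is controlled by the spread of thermal
margins in assembled communities, which in turn depends on the joint
distribution of tolerance limits and local extremes. Only marginal
medians ± 1σ of the limits are published; any Gaussian joint consistent with
them keeps plant niche widths nearly constant (σ_lower ≈ σ_upper), which
compresses the tolerance-scenario survival tail relative to the empirical
data. Users with access to real tolerance datasets can supply them through
the CSV readers and recover the empirical margin structure directly.

## Known limitations

- Distances ignore longitude wraparound and great-circle geometry.
- Per-locality state is stored in dense pool-length arrays: fast at desk
  scale, memory-hungry at the full 100 000-species scale (~GBs for 500
  localities).
- Binary presence only — no population dynamics on links; no top-down
  (consumer-release) effects; no speciation or evolution of phenotypes.
- The trophic pool's shape is an unconstrained stand-in for an unpublished
  empirical list.
- A single climate field; no spatially heterogeneous change scenarios.
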