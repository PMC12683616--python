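# Methods

`flashforest` is an individual-based, spatially explicit forest dynamics
model with an explicit lightning disturbance process, plus the
calibration and ensemble machinery needed to study how tropical forest
structure and composition respond to changing strike frequency.  This
note records the model's assumptions, the parameters that matter, the
design choices made where the design was genuinely open, and what the
synthetic inputs do and do not emulate.

## Domain and state

Space is discretised into 1 m³ voxels.  The ground plane is
`width x length` voxels (default 200 x 200 m, i.e. 4 ha) with a vertical
extent of 50 m; each ground voxel holds at most one living tree, so the
default domain caps the population at 40,000 stems.  A tree's state is
its species, DBH (cm), height, crown radius, crown depth (all from
allometry), leaf area, and a counter of consecutive months with negative
carbon balance.  Height follows the generalised Michaelis-Menten form
H = a·D^b / (k + D^b); crown radius is a power law in DBH and crown depth
a fixed fraction of height (floor of one voxel).

All spatial queries (crown footprints, treefall corridors, lightning
neighbourhoods) use toroidal wrap by default to avoid edge artifacts on
small domains; a hard-edge rule is available.  Distances are Euclidean
between voxel centers, and iteration order is row-major throughout so a
fixed seed reproduces a run bit-for-bit.

## Monthly carbon balance

Canopy light: crowns are "umbrella" stacks of one-voxel-thick disk
layers with uniform leaf area density.  Within each 1 m column the
incident photosynthetic photon flux density (PPFD) is attenuated by
Beer-Lambert (extinction coefficient `k_ext = 0.5`), and the flux
absorbed inside a voxel is attributed to the trees owning leaf area there
in proportion to their LAI share.  Column absorption therefore never
exceeds the incident flux — crowns genuinely compete for light.  For
speed the engine can refresh the light field every `light_update_months`
months (the frequency-sweep runs use 2); the carbon balance itself is
always monthly.

Photosynthesis is the minimum of a light-limited rate (apparent quantum
yield φ times absorbed PPFD) and a capacity-limited rate (Vcmax times a
sunlit-equivalent leaf area, Q10 temperature response), discounted by a
Medlyn-style VPD factor 1/(1 + √D/g1).  Vcmax at 25 °C derives from leaf
nitrogen per area with a centred leaf-%P modifier; species lacking %P use
the same relationship with the modifier fixed at 1 (its mean effect is in
the intercept).  Maintenance respiration has leaf (fraction of Vcmax),
stem (proportional to stem volume) and belowground (scaled to
aboveground) terms; growth respiration is a fixed fraction of the
surplus.  NPP may be negative; negative months increment the starvation
counter and cause no growth.

Positive NPP is allocated in fixed fractions `f_below` / `f_wood` /
`f_canopy` (summing to 1).  Above a size threshold (66 % of the DBH at
which the species reaches 90 % of its asymptotic height) the wood share
is halved — the magnitude of the large-tree growth decline is not pinned
down by data, so the factor 0.5 is a config default.  Wood mass maps to
DBH through stem volume = form_factor · (π/4) · D² · H with wood density
`wsg · 1000 kg m⁻³`; the single-tree API solves (D, H) jointly by fixed
point so carbon is conserved exactly.  Leaf area turns over at the leaf
lifespan, itself a power law in LMA (12 months at LMA = 100 g m⁻²),
capped at a within-crown LAI of 6.

The default coefficients produce a closed-canopy equilibrium of a few
hundred Mg ha⁻¹ AGB with persistent large stems on a 0.25 ha domain
within ~100–150 simulated years.  Absolute fluxes (GPP ≈ 60–80
Mg C ha⁻¹ yr⁻¹) run high relative to eddy-flux estimates for tropical
forest; no result in the package depends on the absolute flux level, but
users fitting to site data should retune `vcmax_n_slope` and
`resp_stem_coef` first.

## Mortality and recruitment

Mortality has three stages each month:

1. **Background + starvation.**  Background probability is
   (m0/12)·(1 − wsg/wsg_max), i.e. the full maximal rate `m0` (yr⁻¹) for
   the softest wood, declining linearly with wood specific gravity.
   Starvation is certain death once consecutive negative-NPP months
   exceed the leaf lifespan.
2. **Treefall.**  Primary treefall is logistic in height (midpoint 38 m,
   width 8 m) scaled to a monthly ceiling of 0.0025, zero at zero height.
   A faller crushes trees in a corridor of length = its height and
   half-width = its crown radius along a uniform random azimuth; crushed
   trees die if shorter than half the faller.  The functional forms are
   explicit config defaults — all that is really established about
   treefall risk at this level of abstraction is that it rises with
   height, so the specific shapes are package choices.
3. **Lightning** (below), when enabled.

Recruitment runs last, so any voxel vacated in the month can refill: all
empty ground voxels whose mean-day light exceeds a compensation threshold
(20 µmol m⁻² s⁻¹) recruit one individual at DBH = 1 cm.  The recruit's
species is drawn from a seedling bank mixing uniform external seed rain
with local production weighted 4·√(mature stems) per species.  The square
root damps the dominant's seed shadow; without it the positive feedback
fixes a single species on small domains in a few decades, which removes
the compositional degrees of freedom the lightning analysis needs.

## Lightning

Strike occurrence: every ground voxel is struck independently each month
with probability λ·10⁻⁶/12 (λ in CG flashes km⁻² yr⁻¹; 12.7 at the
reference site, 95 % CI 10.9–14.5).  A strike targets the tallest living
tree within 15 m of the struck voxel (ties break to the lowest (x, y)
index for replayability); a treeless neighbourhood has no effect.

**CLLR** (community-level lightning risk): a tree of diameter D at
distance r from the struck tree dies with probability

    P_com(r, D) = P_direct · 10^( a · (70 cm / D) · (r / 45 m) ),

with a ∈ [−7, −1].  As typeset in its source the exponent carries a
leading minus sign while the calibration range is negative — mutually
contradictory; this implementation fixes the convention *exponent =
a·(70/D)·(r/45) with a < 0* so probability decays with distance and the
printed search range is honoured, and the CLI reports |a| as the decay
rate.  Mortality is drawn independently for the target (r = 0, risk
exactly P_direct) and every living tree within the flashover cutoff
`r_max` (default 25 m — the radius of the largest observed damage areas
of ~2000 m²; the risk equation itself has no cutoff, so this is a config
default).  Killed trees die instantly and free their voxels; sub-lethal
crown damage is deliberately not modelled.

**SSLR** (species-specific lightning risk) shifts the base-10 log-odds of
P_com by the species parameter Δi (negative = tolerant; species without a
measured value use Δi = 0).  The tolerance summary statistic is the
logistic scaling factor s_i = 1/(1+e^(−Δi)).  Note the base mismatch: s_i
uses base e while the SSLR shift is base 10, so the reading "s_i is the
SSLR risk when the CLLR risk is 0.5" is exact only in base 10.  Both
formulas are implemented exactly as defined and this inconsistency is
documented rather than silently repaired.

The lightning process consumes an RNG stream separate from the
demographic one.  Runs differing only in λ or risk model therefore stay
demographically synchronised until lightning itself alters the stand,
which greatly sharpens paired frequency comparisons on small domains.

## Calibration

Field observations are binned into 5 distance x 3 DBH classes holding
trees at risk, killed, and damaged-but-alive.  Because the eventual fate
of damaged trees is unobserved, a fraction d ∈ [0, 1] of them is assumed
to die: O = killed + d·damaged (one d for all cells; O may be
non-integer and is used as-is).  Predictions are M = n·P_com evaluated at
class representatives — geometric midpoints for distance (0 for the
direct-hit class), arithmetic midpoints for DBH; which representative
enters the risk equation is not specified by the data description, so
this is a documented choice.  The fit minimises R = Σ (M−O)²/O by
exhaustive search on the 101 x 101 lattice (a step 0.06 on [−7, −1],
P_direct step 0.01 on [0, 1], endpoints included; ties break toward
smaller |a| then smaller P_direct).  Cells with O = 0 cannot be scaled
and are skipped with a logged warning.  Goodness of fit is reported as
bias = mean(M−O) and RMSE.

## Uncertainty propagation and the frequency sweep

Six parameters are propagated with ranges φ (0.04, 0.09) mol C mol⁻¹,
m0 (0, 0.03) yr⁻¹, f_below (0.1, 0.5), θ (π/12, 5π/12) rad,
λ (10.9, 14.5), d (0, 1).  The allocation constraint is handled in
cylindrical coordinates: θ is the angle between the wood and canopy axes,
f_wood = (1−f_below)·cosθ/(cosθ+sinθ) and f_canopy its complement, so
f_wood + f_canopy + f_below = 1 exactly.  Draws are the first n points of
an unscrambled Sobol' sequence scaled to the ranges (deterministic;
shorter samples are prefixes of longer ones).  In lightning-enabled runs
the draw's d re-runs the grid search, so each ensemble member uses the
CLLR parameters its own d implies.

The production design runs one 600-year simulation per draw on the 4 ha
domain and averages outputs (AGB, GPP, N10/N30/N60, strike and kill
tallies, species AGB) over the final 50 years.  The frequency sweep
crosses λ ∈ {9, …, 23} with 1000 parameter sets — 15,000 runs, a
cluster-scale experiment.  The package ships the design as a manifest
generator with per-row deterministic seeds (CRC-32 of run id, λ,
parameter index; independent seeds per run); scale knobs (domain,
duration, ensemble size) let the same machinery run at desk scale.
Consistency filtering selects runs whose AGB, GPP, N10 and N60 all fall
inside user-supplied observational intervals; the intervals are inputs,
not bundled, since they derive from site data not distributed here.
A transient mode varies λ(t) linearly between two epochs for
out-of-equilibrium experiments.

### Desk-scale problem sizes

The test suite exercises the sweep at 50 x 50 m, 300 years, 20 Sobol'
parameter sets, with λ ∈ {9, 23} under both risk models and common
random numbers across arms — sizes chosen so the full suite completes on
a laptop while the qualitative equilibrium responses (AGB decline under
CLLR, its attenuation under SSLR, the kills-per-strike saturation) are
resolved in ensemble medians.  At this scale single runs are strongly
stochastic: a 0.25 ha stand holds only a dozen emergent trees and a
300-year run sees ~5–20 strikes, so paired designs and medians are
essential, and per-run compositional outcomes should not be
over-interpreted.

## Synthetic inputs

The generators stand in for inputs that cannot be redistributed: a site
trait census (96 + 7 species), a trait database, a 16-year half-hourly
meteorological climatology, and field strike surveys.

- **Species table** (default 27 species, ~40 % with non-zero Δi,
  mirroring the measured-tolerance census shape): traits are drawn from
  plausible tropical ranges with a weak stature–wood-density covariance
  so equilibria contain large, persistent trees.  Two species form a
  deliberate near-isogenic pair: copies of a tall, productive,
  dense-wooded emergent archetype differing only in lightning tolerance
  (Δ = 0 vs Δ = −2) and a 3 % stature edge in the tolerant twin's
  favour.  This emulates a forest whose leading emergent is
  lightning-tolerant — the situation in which community-level and
  species-specific risk models diverge most — and gives compositional
  acclimation a resident candidate rather than requiring a rare species
  to invade a 0.25 ha stand within 300 years, which drift essentially
  forbids.  Remaining tolerant species are scattered at random;
  intolerant ones are biased toward tall statures.
- **Forcing**: a smooth sinusoidal diurnal PPFD arc (06:00–18:00),
  diurnal temperature and VPD cycles, and a mild seasonal modulation;
  12 months × 48 half-hours, deterministic per seed.  It contains no
  interannual variability, cloud stochasticity, or covariance structure
  between drivers — matching the repeating-climatology design of the
  simulator, but meaning the tests say nothing about weather-driven
  variance.
- **Binned mortality**: counts drawn from known CLLR parameters.  Each
  tree is lightning-affected with probability P/(c + d_true(1−c)) with
  immediate-death share c = max(0.6, P), so E[killed + d_true·damaged] =
  n·P exactly — the construction that makes calibration recovery a
  well-posed round trip.  A fixed dataset (a = −3.04, P_direct = 0.85,
  d = 0.6, 400 trees/cell, seed 42) ships as the default calibration
  input.

Passing tests on these fixtures demonstrates that the algorithms are
implemented correctly and that the documented mechanisms operate; it
does not validate the model against real forest observations.

## Numerical choices and degenerate inputs

- Strike counts per month are drawn as one Binomial(n_voxels, p) with
  uniform voxel placement — exactly equivalent to independent per-voxel
  Bernoulli draws, and O(1) per month.
- SSLR with Δ = 0 short-circuits to the community probability bit-exactly
  so shared-stream equivalence tests hold to the last ulp.
- P_com boundary handling in the log-odds shift: 0 → 0 and 1 → 1 for any
  finite Δ.
- λ large enough to push the per-voxel monthly probability above 1 is
  rejected rather than clipped.
- Empty grids, treeless strike neighbourhoods, all-zero observation
  tables, and degenerate allocation angles (θ = 0, π/2) are rejected or
  return explicit empty results, never silently coerced.

## Known limitations

No soil water, nutrient cycling, lianas, fire, wind co-disturbance,
interannual climate variability, or sub-lethal crown damage carry-over;
damaged-tree fate enters only through the calibration parameter d.
Crown geometry is an umbrella disk; sub-voxel positions and topography
are out of scope.  The physiology is a structurally faithful but
coefficient-simplified gap-model chain, not a leaf-level gas-exchange
model, and its absolute fluxes run high (see above).  Compositional
results at desk scale are ensemble statements, not single-run
predictions.
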