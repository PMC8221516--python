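# Methods

This note records the model structure, the defaults that matter, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Within-patch demography

Each habitat patch runs a density-independent, post-breeding-census
2-stage projection matrix over annual steps,

    N(t+1) = [[s_j f, s_a f], [s_j, s_a]] N(t),

with juveniles aged 0–1 and adults thereafter. Because both stages
reproduce at the same rate, the matrix is rank-1-fecund (determinant
zero) and its dominant eigenvalue is λ = s_a + s_j f; one matrix
multiplication also projects any state onto the stable stage ray
(n_j : n_a = f : 1). The analytic toolkit uses these identities:
sensitivities (1, s_j) and elasticities (s_a/λ, s_j f/λ) of λ with
respect to (s_a, f), which always sum to one for this structure.

Habitat quality q ∈ [0, 1] degrades each maximal vital rate through
c = 1 − (1 − q)^α. Defaults α_f = 3 (fecundity) and α_s = 5 (survival):
survival saturates faster with quality than fecundity does, which puts
the source–sink transition (λ(q) = 1, found by bisection to |Δq| <
1e-6) near q ≈ 0.31 for the packaged gnatcatcher rates. Pesticide
exposure multiplies the whole matrix by the season survival s_p
(an independent competing risk on top of background survival) and
replaces f by the exposed seasonal fecundity f_e; with s_p = 1 and
f_e = f the exposed matrix is bit-identical to the unexposed one.

Packaged vital rates (best habitat): s_j = 0.4314, s_a = 0.52,
f = 2.26 female offspring/female. These are deliberately optimistic
rates that apply only at q = 1; density dependence adds further
effective juvenile mortality through dispersal and culling.

Within-patch abundances are continuous (expectation dynamics).
Stochasticity enters only through the yearly environmental multiplier,
the pesticide realization maps, and the individual-based dispersal
step, where juvenile counts are integerized by probabilistic rounding
(floor plus a Bernoulli draw on the fraction, seeded).

## Exposure model

One growing season, 1-hour timestep, dietary route only. Inhalation,
dermal and drinking-water uptake are deliberate omissions: hooks exist
in the configuration surface but contribute zero dose. The practical
consequence is that acute mortality predictions here are lower bounds
for chemicals whose risk is driven by inhalation; for the packaged
acute stressor the on-field season survival is ≈ 0.6–0.7 rather than
a total kill.

Parameters and defaults, with reasons:

- **Unit residues** (mg a.i./kg fresh diet per lb a.i./acre): small
  insects, mean 65 (upper bound 135 available), the standard
  Kenaga/Fletcher nomogram values for an insectivore's diet.
- **Foliar half-life** 35 d: the conventional default when no
  dissipation study is available; residues decay first-order and
  applications superpose.
- **Residue variability** σ_log10 = 0.23, median-1 lognormal per day:
  daily residue heterogeneity on food items.
- **Food intake** FI = 0.398 · W^0.850 g dry matter/day (passerine
  allometry). Unit residues are expressed per kg *fresh* diet, so
  ingestion uses fresh-weight intake FI/(1 − m) with diet moisture
  m = 0.7 (insect prey); omitting this conversion understates dose
  roughly threefold.
- **Feeding pattern**: two truncated Gaussians (σ = 1.5 h) centred 1 h
  after sunrise and 1 h before sunset, renormalised over daylight;
  night intake is exactly zero.
- **On/off-field foraging**: two-state Markov chain with stationary
  on-field fraction and lag-1 autocorrelation as parameters. The
  default profile forages entirely on-field (fraction 1): the exposure
  model describes the *exposed* sub-population, and landscape-level
  dilution is handled by the crop-proportion mixing (below). Setting
  the fraction below 1 models partial field use instead.
- **LD50 scaling**: LD50_adj = LD50 · (W/W_test)^(x−1) with the
  pesticide-specific scaling factor x (default 1.15); test-species
  weights 1170 g (mallard) and 178 g (bobwhite).
- **Acute endpoint**: probit mortality Φ(slope · log10(dose/LD50_adj))
  on the maximum rolling 24-h ingested dose, slope default 4.5. No
  toxicokinetic elimination (the 24-h window is the implicit clearance
  assumption).

Deterministic mode (median residues, stationary foraging) is used for
effects curves and is exactly reproducible; Monte Carlo mode averages
independent females under a seeded generator.

## Nest productivity model

A daily state machine per female: waiting → laying (4 d) → incubation
(14 d) → nestling (16 d), with renesting after a 3-d wait on failure
and a 21-d wait after fledging, inside a nest-initiation window of
days 84–196 (late March to mid-July). Nests started inside the window
run to completion beyond it. Clutch 4, half female, so each successful
brood fledges 2 female offspring. Nest initiation is deterministic
when the window is open (probability parameter available). Whole-nest
failure occurs when the day's dietary concentration exceeds the active
phase's NOAEL — failures are unit events, never per-egg — and the
packaged chemicals apply their single dietary NOAEL to all three
phases, since no phase-specific mapping is available.

Daily nest survival is not a free parameter: it is calibrated by
bisection (tolerance 1e-4) so that *unexposed* seasonal fecundity
equals the annual fecundity of the demographic matrix, 2.26. The
calibrated value, 0.956711/day, is stored in the species fixture and
re-derived in tests. The window fits at most three successful cycles,
so fecundity is bounded by 6.

Two evaluation routes exist and are tested against each other: a
per-female Monte Carlo simulation, and an exact expectation by forward
propagation of the state distribution (dynamic programming over
(phase, day-in-phase) states). The daily lognormal residue noise is
integrated analytically in the exact route as an exceedance
probability Φ(log10(C_median/NOAEL)/σ). This pathway matters: the
chronic stressor's median concentration peaks *below* its NOAEL
(≈ 1.9 vs 4.62 mg/kg diet at label rates), so all of its reproductive
effect comes from the upper tail of daily residue variability
accumulated over a ~34-day nest; a hard threshold on the median would
predict no effect at all.

An optional death day truncates broods fledged after acute mortality;
at the population level the competing-risk multiplication by s_p in
the projection matrix already removes a dead female's reproduction,
so the effects-curve pipeline leaves this off by default.

## Effects curves and landscape realization

For each chemical the label's seasonal maximum is split evenly into
2, 3 or 4 applications at the minimum interval, and the first
application date is scanned weekly over days 1–274. Each scan point
runs the deterministic exposure model (s_p) and the exact nest
enumeration (f_e), so curves carry no Monte Carlo error. Fecundity
returns exactly to baseline once the first application falls after
window end + nest cycle (day ≈ 230): the last window-initiated nest
has fledged before any residue appears. Interpolation between weekly
nodes is linear, clamped outside the grid. Curves cache to CSV
(lossless round trip), so the population engine can run from
user-supplied curves.

A yearly realization map assigns each cropped patch an independent
uniform draw of (number of applications ∈ {2, 3, 4}) × (first date on
the scan grid); uncropped patches stay unexposed. Patch-level expected
vital rates use binomial mixing E(v) = p v_e + (1 − p) v_u with p the
patch's crop proportion; mixing is done on maximal-habitat rates and
the habitat coefficient is applied afterwards (the alternative —
habitat-scaling v_e before mixing — is algebraically identical here
because both rates are scaled by the same c).

## Landscape, dispersal, scenarios

Flat-top hexagons of 0.86 ha (pitch from A = (√3/2)·pitch², ≈ 99.7 m);
raster cells are assigned to hexagons by nearest centroid (exact for a
hex lattice) and averaged. Patches are 13 × 7 blocks of hexagons —
exactly 91, ≈ 79 ha — with q and p the member means and K = 0.062 ×
member count (0.86/0.062 ≈ 14 ha per territory); boundary and
missing-data blocks simply have fewer members.

Dispersal: patches with N > K shed N − K juveniles (never more than
are present; adults never move). Each disperser draws a maximum
distance ~ U(0.5, 10) km, then walks hexagon to hexagon keeping its
heading with probability 0.9 (else turning uniformly among the six
directions), settling at the first patch with N < K — occupancy is
updated online in randomized disperser order to avoid order artifacts
— or stopping where it stands when the distance budget runs out;
walkers stranded outside any patch are lost. Remaining overflow is
culled back to N ≤ K. The walk's step length and turning kernel are
package defaults, not observed quantities.

Yearly order of operations: environmental multiplier → effective vital
rates (mixing, habitat coefficients, s_p) → matrix step → juvenile
integerization, dispersal, culling → census (breeding pairs reported
as floor(adults/2)). The environmental multiplier is one uniform draw
on [1 − v, 1 + v] (v = 0.10) per patch per year, applied identically
to s_a, s_j and f (survival clipped at 1); a flag switches to a single
landscape-wide draw. A uniform bounded distribution was chosen because
the ±10 % specification bounds the variability; patches are
independent by default because no spatial correlation is specified.

Scenario design: 100 realization maps are generated once per master
seed; each trial fixes a 50-year resample (with replacement) of that
pool and runs 10 replicate trajectories against it; 10 trials by
default. The master seed spawns independent, logged sub-streams
(NumPy SeedSequence) for maps, trials and replicates, so full runs are
bit-reproducible.

## Synthetic landscapes

The generator emulates the *statistical* texture of a habitat map —
spatial autocorrelation (Gaussian-smoothed white noise,
rank-transformed), a target fraction of suitable cells (q > 0.5,
default 13 %, matched exactly by construction), and clumped crop
fields (square blocks seeded preferentially on poor habitat, default
10 % cover, trimmed to the target) — but not real geography: no range
polygon, no coastline gradient, no correlation between crop geometry
and real agronomy. Default test extent is 8 km × 8 km at 60 m
resolution (≈ 9,000 hexagons, ≈ 100 patches), chosen so full 50-year,
multi-replicate runs complete in seconds; the generator scales to the
30 km default extent unchanged.

Consequently, passing scenario tests demonstrate *structural* and
*directional* behaviour — capacity enforcement, reproducibility,
source–sink structure, and the ordering of control vs chronic vs acute
stressor outcomes — not absolute abundances of any real population.
Scenario contrasts are measured as the mean total abundance over the
final five years across all trials and replicates, which damps
single-year environmental noise.

## Numerical choices and degenerate inputs

- Bisection tolerances: 1e-6 on q (source–sink threshold), 1e-4 on
  fecundity (nest-survival calibration).
- Eigenvalues via `numpy.linalg.eigvals`, taking the maximum real part
  (non-negative matrices); verified against power iteration to 1e-10.
- Zero dose gives survival exactly 1 (no log of zero); empty
  application schedules short-circuit to no exposure.
- q = 0 zeroes the projection matrix; λ = 0 makes elasticities
  undefined (raised as an error); no λ = 1 crossing on [0, 1] raises
  rather than returning a boundary value.
- Dispersal respects N ≤ K up to the integer-rounding convention
  (±1 bird where K is fractional).
- Rasters use NaN internally for nodata; ESRI ASCII grids round-trip
  exactly via `repr` floats.

## Known limitations

- Dietary exposure only; acute mortality is understated for chemicals
  with substantial inhalation or dermal uptake.
- No spray-drift gradient: a patch's exposed fraction equals its crop
  proportion, with no edge effects.
- No per-egg effects, eggshell-thinning dose-response, or
  density-dependent nest survival; NOAEL exceedance fails whole nests.
- Single crop per patch; application scenarios are uniform draws with
  no agronomic calendar.
- Only juveniles disperse, and the study extent is closed (no
  immigration or emigration across its boundary).
- Two stages only; no pre-breeding census variant.
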