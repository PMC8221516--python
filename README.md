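# avirisk

Spatially explicit population-level pesticide risk modelling for birds,
built around the California Gnatcatcher (*Polioptila californica*, CAGN)
case study: a threatened, insectivorous songbird of southern-California
coastal sage scrub whose habitat abuts treated cropland.

The package is aimed at ecological risk assessors and population
ecologists who need to translate individual-level pesticide toxicity
data (LD50, dietary NOAEL, application rates from the product label)
into projected multi-decadal population trajectories over a landscape.

## The model

Three linked components:

1. **Dietary exposure (hourly, one growing season).** Applications add
   foliar residues (unit-residue convention, mg a.i./kg diet per
   lb a.i./acre) that decay first-order with the foliar half-life, with
   median-1 lognormal daily variability. A female's ingested dose
   follows allometric food intake (FI = a·W^b, dry matter, converted to
   fresh weight by diet moisture), a bimodal post-sunrise/pre-sunset
   feeding pattern, and a two-state Markov chain for on/off-field
   foraging. The maximum rolling 24-h dose enters a probit
   dose-response against the body-weight-scaled LD50, giving the season
   survival probability *s_p*.

2. **Nest productivity (daily Markov chain).** Females progress through
   laying, incubation and nestling phases inside a nest-initiation
   window, fail naturally with probability 1 − (daily nest survival) per
   day, fail outright as a whole nest whenever the day's dietary
   concentration exceeds the active phase's NOAEL, and renest while the
   window is open. The expected seasonal fecundity under exposure, *f_e*
   (female offspring per female), is computed exactly by dynamic
   programming (a Monte Carlo simulator cross-checks it). Scanning a
   moving weekly window of first-application dates yields per-chemical
   **effects curves** (date, number of applications) → (*s_p*, *f_e*).

3. **Landscape population projection (yearly).** Habitat-quality and
   crop rasters are resampled to 0.86-ha hexagons, aggregated into
   91-hexagon (~79 ha) patches with carrying capacity K = 0.062
   birds/hexagon. Each patch runs a post-breeding-census 2-stage matrix

       N(t+1) = [[s_j f, s_a f],
                 [s_j,   s_a  ]] · s_p · N(t)

   with vital rates degraded by habitat quality through
   c = 1 − (1 − q)^α (α = 3 for fecundity, 5 for survival), exposed and
   unexposed rates mixed by the patch's crop proportion p
   (E(v) = p·v_e + (1 − p)·v_u), ±10 % correlated environmental noise,
   and density-dependent juvenile dispersal: over-capacity juveniles
   walk a highly autocorrelated path (maximum distance ~ U(0.5, 10) km),
   settle in the first patch with N < K, and are culled if none is
   found. Scenarios follow a realization/trial/replicate design (100
   random pesticide-use maps, trials of fixed 50-year resamples, 10
   replicates each).

The matrix's dominant eigenvalue has the closed form λ = s_a + s_j·f,
with sensitivities (∂λ/∂s_a, ∂λ/∂f) = (1, s_j) and elasticities
(s_a/λ, s_j·f/λ). A synthetic-landscape generator (autocorrelated
habitat fields, clumped crop blocks) makes the whole pipeline runnable
with no external GIS data.

## Worked example

```python
import numpy as np
from avirisk import (
    packaged_species, packaged_chemical, build_projection_matrix, finite_rate,
    elasticities, source_sink_threshold, build_effects_curve, interpolate_effect,
)

species = packaged_species()                      # CAGN fixture
lam = finite_rate(build_projection_matrix(species.vitals, q=1.0))
e_sa, e_f = elasticities(species.vitals)
q_star = source_sink_threshold(species.vitals, species.coeffs)
print(f"finite rate of increase (q=1): {lam:.3f}")
print(f"elasticities (adult survival, fecundity): {e_sa:.2f}, {e_f:.2f}")
print(f"source-sink habitat threshold: q* = {q_star:.3f}")

chem = packaged_chemical("survival_stressor")
curve = build_effects_curve(chem, 3, species.breeding, species.forager)
apr1 = interpolate_effect(curve, 91)
print(f"survival stressor, 3 applications starting Apr 1: "
      f"s_p = {apr1.s_p:.3f}, f_e = {apr1.f_e:.2f} (baseline {curve.f_baseline:.2f})")
```

prints

```
finite rate of increase (q=1): 1.495
elasticities (adult survival, fecundity): 0.35, 0.65
source-sink habitat threshold: q* = 0.314
survival stressor, 3 applications starting Apr 1: s_p = 0.666, f_e = 1.88 (baseline 2.26)
```

In ideal habitat the population grows strongly (λ ≈ 1.5); proportional
changes in fecundity matter almost twice as much as proportional
changes in adult survival (0.65 vs 0.35); and a patch flips from
population sink to source once habitat quality exceeds roughly 0.31.
Three 1 lb/acre applications of the acute stressor starting April 1
leave a field-foraging female a 67 % chance of surviving the season and
cut her expected fecundity from 2.26 to 1.88.

The CLI drives the same pipeline end to end:

```sh
avirisk fixtures --seed 1 --output-dir fix        # synthetic rasters + configs
avirisk curves --chemical survival_stressor       # effects-curve CSV cache
avirisk simulate --habitat fix/habitat.asc --crop fix/crop.asc \
    --chemical survival_stressor --seed 1
avirisk summarize results/trajectories_survival_stressor.csv
```

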