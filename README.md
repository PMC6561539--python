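# camsecr

Stratified maximum-likelihood **spatially explicit capture-recapture**
(SECR) for multi-array camera-trap surveys of individually identifiable
carnivores, plus the supporting machinery such a landscape-scale density
study needs: a Bayesian multi-species occupancy model that turns prey
detections into an array-level *prey encounter index*, AIC model
selection with 85% Wald intervals for screening uninformative
parameters, and reporting-unit derived quantities (mean density per
100 km², per-array movement scales, 95% home ranges).  A first-class
synthetic-data module generates complete surveys with the same
statistical structure, so the whole pipeline runs and is tested without
any field data.

## Who this is for

Quantitative ecologists estimating large-carnivore density from camera
traps who need: covariates on density (habitat, distance to a reserve
boundary, prey availability), detection modelled as a half-normal
function of distance between trap and activity centre, independent trap
arrays treated as strata of one landscape model, and simulation-based
checks that the estimator recovers known truth at their survey's scale.

## The model in brief

Detection of an individual with activity centre *s* at trap *j* on one
daily occasion is half-normal,

    p(s, j) = p0_j · exp(−d(s, j)² / (2 σ_j²)),
    logit(p0_j) = α0 + α'·x_j,      log(σ_j) = δ0 + δ'·x_j,

and activity centres follow an inhomogeneous Poisson point process on a
discrete habitat mask (500 m pixels, 6 km buffer) with

    log Λ_g = β0 + β'·x_g,          N_r ~ Poisson(Λ_r),

fitted by maximizing the full Poisson-form SECR likelihood summed over
independent array strata.  Candidate covariate structures are ranked by
AIC with Akaike weights; near-best models are screened for a single
uninformative extra parameter via 85% Wald intervals.  Home ranges use
the bivariate-normal 95% contour, π(σ√5.99)².

## Worked example

```python
import math
from camsecr import (SimConfig, simulate_study, ModelSpec, fit_ml,
                     rank_models, build_report)

# a complete synthetic six-array survey at the default study scale
data, truth, prey = simulate_study(SimConfig(rng_seed=1))
print(data.n_individuals, "detected individuals")

m_boundary = ModelSpec(density=("d2boundary",), p0=("d2river",),
                       sigma=("array",), name="boundary")
m_null = ModelSpec(p0=("d2river",), sigma=("array",), name="null")
fits = [fit_ml(m, data) for m in (m_boundary, m_null)]

print(rank_models(fits).table[["model", "k", "loglik", "AIC", "dAIC",
                               "weight"]].to_string(index=False))
print(build_report(fits[0]).render())
```

Output (seed 1):

```
49 detected individuals
   model  k       loglik         AIC     dAIC   weight
boundary 10 -1069.446064 2158.892128 0.000000 0.936355
    null  9 -1073.134738 2164.269475 5.377347 0.063645
Derived quantities
------------------
Mean density: 4.78 / 100 km^2  (85% CI 3.74-6.11)

Array          sigma (m)   95% HR (km^2)
Idete             2025.9            77.2
Lumemo            2334.7           102.6
Mbatwa            1524.5            43.7
Mwanihana         1036.9            20.2
Ndundulu          1122.8            23.7
Ruipa             2043.7            78.6
mean                                57.7
```

The boundary-distance model is preferred (ΔAIC 5.4 over the null, Akaike
weight 0.94), the estimated mean density of 4.78/100 km² brackets the
generating truth of 4.22/100 km² within its 85% interval, and per-array
movement scales σ (metres) translate into 95% home ranges of 20–103 km².

A command-line pipeline wraps the same functions:

```bash
camsecr simulate      --config config.yml --seed 1 --out run/
camsecr fit-occupancy --config config.yml --out run/
camsecr fit-secr      --config config.yml --out run/
camsecr select        --config config.yml --out run/
camsecr predict       --config config.yml --out run/
camsecr report        --config config.yml --out run/
```

All interchange formats are plain text (CSV capture histories, trap
layouts with usage strings, ESRI ASCII rasters, YAML configuration).

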