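# ptarmigan

Partial-migration analysis for radio-tagged willow ptarmigan (*Lagopus
lagopus*) — and, more generally, for any telemetry study where sparse VHF
fixes must be turned into migrant/resident calls and downstream
biostatistics.

In a breeding partially migratory population, migrants and residents share a
winter area but breed apart. Given only a handful of located positions per
bird and season, the analysis chain implemented here is:

1. **Home-range baselines.** GPS tracks are screened with a
   consecutive-distance spike filter (a fix at time *t* is an outlier when
   the step into it exceeds twice the distance between its neighbours at
   *t−1* and *t+1*), then summarized as 95% minimum convex polygons (MCP).
   The mean winter MCP (default 4.08 km², radius 1140 m) and the median
   summer polygon (default 0.058 km², radius 136 m) define circular range
   proxies for every bird.
2. **Classification.** Each bird-season (winter = January–March, summer =
   May–July) collapses to an activity center — nest-weighted in summer, with
   the nest and the mean of all other positions given equal weight. Two
   circular ranges cannot overlap when their centers lie further apart than
   the sum of their radii (1140 + 136 = **1276 m**), so a
   consecutive-season displacement > 1276 m is a **migrant** transition, and
   anything at or below it a **resident** one.
3. **Repeatability.** Whether migration is a fixed individual strategy is
   quantified as the intraclass correlation of log movement distance from a
   random-intercept linear mixed model fit by REML:
   *R = σ²α / (σ²α + σ²ε)*, with a parametric-bootstrap percentile CI
   (n = 1000). Agreement repeatability uses an intercept-only fixed part;
   adjusted repeatability adds age class.
4. **State-dependent models.** First-spring decisions are modeled with
   binomial GLMs (migrate ~ weight × age, weight z-scored), distances with
   Gaussian linear models, clutch sizes with a mean-parameterized
   Conway–Maxwell–Poisson regression (dispersion ν > 1 captures the
   underdispersion typical of clutch data), and nest fate with binomial
   GLMs. Candidate sets are ranked by AICc
   (−2ℓ + 2k + 2k(k+1)/(n−k−1)) with Akaike weights.

A fully seeded synthetic-data generator (`ptarmigan.simdata`) reproduces the
study design — two capture sites, weight- and age-dependent logistic
migration decisions, high between-season strategy fidelity, GPS tracks with
injected position spikes, CMP clutches — with known ground truth, so every
stage is testable without any field data.

## Worked example

```python
from ptarmigan import (SimConfig, simulate_population, classify_population,
                       summarize_transitions, agreement_and_adjusted)

cfg = SimConfig(seed=42)                      # 100 birds, 5 years
fixes, birds, nests, truth = simulate_population(cfg)
transitions, centers = classify_population(fixes, nests)
print(summarize_transitions(transitions).to_string(index=False))

agree, adj = agreement_and_adjusted(transitions, birds, n_boot=1000, seed=42)
print(f"agreement R = {agree.R:.2f} (95% CI {agree.ci_low:.2f}-{agree.ci_high:.2f})")
print(f"adjusted  R = {adj.R:.2f} (95% CI {adj.ci_low:.2f}-{adj.ci_high:.2f})")
```

```
 year  residents  migrants  total  pct_migrants
 2015          6        16     22            73
 2016          4        11     15            73
 2017          7        10     17            59
 2018          9        18     27            67
 2019          5        14     19            74
total         31        69    100            69
agreement R = 0.72 (95% CI 0.64-0.79)
adjusted  R = 0.73 (95% CI 0.64-0.79)
```

The summary counts first-spring decisions per year (69% migrants overall
here); the repeatability near 0.7 reflects the generator's 0.9
between-season strategy fidelity.

The same pipeline is available from the shell:

```sh
ptarmigan simulate --out data/ --seed 42
ptarmigan classify --fixes data/fixes.csv --nests data/nests.csv --out transitions.csv
ptarmigan repeat --transitions transitions.csv --birds data/birds.csv --nboot 1000 --seed 42
ptarmigan models --transitions transitions.csv --birds data/birds.csv --nests data/nests.csv --out models/
```

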