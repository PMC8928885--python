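# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind the package, in the spirit of a methods
appendix.

## Classification model

The classifier assumes every female shares a common circular home range per
season: winter area `A_w` (default 4.08 km²) and summer area `A_s` (default
0.058 km²), each centered on the bird's seasonal activity center. Radii are
`round(sqrt(A × 10⁶ / π))` meters — 1140 m and 136 m at the defaults. Two
circles cannot overlap when their centers are further apart than the sum of
the radii, so the migrant threshold is 1276 m. The boundary uses a strict
inequality: a displacement of exactly 1276 m still permits (tangential)
overlap and is classified resident.

Seasons are calendar windows: January–March (winter) and May–July (summer);
fixes outside both windows are ignored by the classifier. Capture positions
fall in February–March and therefore count as winter fixes. Activity centers
are arithmetic means of the season's fixes; for nesting hens the summer
center is the midpoint of the nest location and the mean of all other
positions, i.e. the nest carries weight equal to the rest of the season
combined. (We read "equal weights to the nest and the sum of all other
positions" as weighting the nest against their *mean*; a literal sum is not
a location.)

Transitions are consecutive-season pairs only (winter→summer of a year,
summer→winter of the next). Birds missing one season of a pair contribute no
transition. Each bird's earliest winter→summer pair is flagged
`is_first_spring`; the state-dependent models use only those rows to avoid
pseudo-replication.

### GPS screening

A GPS fix at interior index `t` is an outlier iff
`dist(t−1, t) > 2 × dist(t−1, t+1)`. The rule is applied in a single pass
over the original sequence — flags do not cascade, and the first/last fixes
are never flagged. A single-pass application matches a one-shot cleaning
step; iterating to a fixed point could eat genuine range shifts on noisy
tracks.

### MCP convention

The `percent` MCP retains the `k = max(3, floor(percent × n / 100))` fixes
nearest the arithmetic mean of all fixes, distance ties broken by earlier
timestamp, and returns the convex hull (counter-clockwise) with its shoelace
area. Floor-with-minimum-3 is one of several quantile conventions in use;
it is fixed here and used consistently, including in the calibration
constants below. The winter baseline averages per-bird 95% MCP areas
(arithmetic mean); the summer baseline takes the median across birds of the
100% hull of each bird's summer fixes.

All coordinates are assumed planar metric (e.g. UTM 33N). At the ≤50 km
scale of the analysis, planar distance error is negligible, so no CRS
handling is included.

## Repeatability

Log movement distance, `log(distance_m + 1)`, is modeled with a single
random intercept per bird. True zero displacements occur (a bird can be
located at the identical activity center), so the +1 m offset keeps the log
finite; it sits 3–4 orders of magnitude below migrant distances and is
documented in all outputs. Only birds with ≥2 observed seasonal decisions
enter.

The REML fit profiles the variance ratio θ = σ²α/σ²ε: for fixed θ the GLS
coefficients, the residual variance, and the restricted likelihood all have
closed forms through per-group sums, leaving a bounded 1-D search over
log θ (absolute tolerance 1e−10, search window e⁻³⁰–e¹⁶) plus an explicit
check of the θ = 0 boundary. Repeatability is R = σ²α/(σ²α+σ²ε);
R is undefined (an error) when the total variance is zero.

The confidence interval is a parametric bootstrap: simulate group intercepts
and residuals from the fitted normal components, refit, recompute R, and
take percentile bounds (default 95%, n = 1000). Percentile intervals are the
standard choice in repeatability workflows; BCa was not implemented. Failed
refits are skipped and counted; more than 10% failures aborts. A binary
(decision-level) repeatability model is deliberately absent — with few
observations per bird, binomial variance-component fits routinely fail to
converge, so the distance-based measure is the supported one.

## Regression models and AICc

* **Migration decision** (migrant = 1): binomial GLM, logit link, fit by
  IRLS to gradient norm < 1e−10. Complete or quasi-complete separation is
  detected (diverging linear predictor, |η| > 15–30) and attached to the fit
  as a warning rather than an error. Candidate set: weight×age interaction,
  weight, intercept, age, weight+age.
* **Movement distance**: Gaussian identity-link model on
  `log(distance_m + 1)` (the same offset convention as the repeatability
  model), same candidate set. The reported log-likelihood is full ML (σ²
  estimated with denominator n) so AICc is comparable across candidates; σ²
  counts toward k.
* **Clutch size**: mean-parameterized Conway–Maxwell–Poisson regression,
  log link. The CMP pmf is `P(Y=j) ∝ λʲ/(j!)^ν`; ν > 1 gives variance below
  the mean. The natural parameter λ is solved from the mean by safeguarded
  Newton on log λ (|mean−μ| < 1e−8; the derivative of the mean in log λ is
  the variance, so the map is monotone). The normalizer is accumulated in
  log space over an adaptive truncated support (tail < 1e−12, cap 10⁴
  terms). The regression maximizes the joint likelihood over (β, log ν) by
  BFGS from a Poisson-GLM start, with a Nelder–Mead polish on demand; ν
  counts toward k. Candidate set: intercept, age, weight, strategy, and
  their sums (8 models).
* **Nest fate** (hatched = 1): binomial GLM over the same 8-model set.

The first-spring tables have one row per bird, so a per-bird random effect
would be inert in these models; they are implemented as fixed-effects GLMs.
Year does not appear in the clutch/nest candidate sets. Body weight is
z-scored (n−1 denominator) on each analysis subset.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); it is an error when n ≤ k+1. Akaike
weights are `exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)`; tables sort by AICc with ties broken
by smaller k, then label. Parameter counts: binomial intercept-only k = 1;
Gaussian intercept-only k = 2 (residual variance); CMP intercept-only k = 2
(dispersion).

## Synthetic-data generator

The generator emulates the study design, not any particular data set:

* **Population.** Default 100 birds over 5 years, captured in winter at two
  sites 20 km apart (capture year uniform over the study years). Age class
  juvenile/adult with p = 0.5; winter weights N(590, 30²) g for juveniles
  and N(600, 30²) g for adults, rounded to 5 g as a field spring scale
  would.
* **Decisions.** The first seasonal decision is Bernoulli with
  logit⁻¹(β₀ + β_w z + β_ad·ad + β_w:ad z·ad), z the population-standardized
  weight. Defaults β = (1.0, −1.5, 0.0, 1.5): juveniles migrate less the
  heavier they are; adults are flat at ~73% migration. Later decisions
  repeat the previous one with probability 0.9 (strategy fidelity), else are
  redrawn from the rule.
* **Displacements.** Migrant displacements are log-normal (meanlog 8.9,
  sdlog 0.65 in meters: median ≈ 7.3 km, mean ≈ 9 km, matching the reported
  distance scale of the study system), at a uniform random bearing; the
  config is rejected unless ≥99% of that distribution clears the 1276 m
  threshold. Resident displacements are uniform on [0, 0.8 × threshold], so
  truth labels stay unambiguous near the boundary.
* **Fix scatter.** VHF fixes are isotropic Gaussian around the seasonal
  center. The per-axis scatter is solved from the configured baseline areas
  through a stored constant: the expected 95% MCP area of 100 Gaussian fixes
  is 12.442 × the per-axis variance (Monte Carlo, 20 000 replicates, SE
  0.01). The constant is stored, not re-derived at run time.
* **Sampling density.** Default 6–10 fixes per bird-season. This is denser
  than typical VHF field effort (often 1–2 winter positions); the choice is
  a deliberate idealization so that activity-center error (≈ σ/√n ≈ 200 m
  per axis in winter) stays small against the 255 m gap between the largest
  resident displacement and the threshold. With one or two winter fixes the
  center error would be of the same order as that gap and no classifier
  could recover the truth reliably — a caveat that applies equally to sparse
  real data.
* **GPS tracks.** Three GPS birds carry one dense winter track each
  (4-h interval, ~500 fixes): a correlated random walk with gamma step
  lengths (shape 8), wrapped-normal turning (sd 0.5 rad), and a gentle
  heading bias toward the center (strength 0.3 within a confinement radius
  of 10 mean steps). The mean step is solved from the winter area through a
  second stored constant (95% MCP of a 540-fix track = 174.9 × step², Monte
  Carlo, 600 replicates). Injected spikes displace single fixes by
  `outlier_multiplier` × the mean step (default 20×), kept ≥3 fixes apart
  and off the track ends so each spike is isolated, as GPS glitches are.
  GPS birds have a single season and therefore never enter the transition
  analyses — they only inform the winter baseline.
* **Nesting.** 90% of summering birds nest; the nest sits one summer-scatter
  draw from the center and contributes both a nest fix and a nest record.
  Clutch sizes are CMP(μ = 10, ν = 2) (underdispersed, as clutch data are);
  fate is hatched with p = 0.7. Optional effect-size knobs
  (`strategy_effect_eggs/hatch`, default 0) tie nesting outcomes to
  strategy; at 0 the outcomes are independent of strategy by construction.

Everything derives from one `numpy` generator seeded from the config, so a
config reproduces its tables bit-for-bit.

**What passing tests do and do not show.** The generator produces isotropic
Gaussian scatter, season-stationary centers, no mortality or missed
relocations, no triangulation bias, and idealized fix density. Recovery of
truth under these conditions validates the pipeline's logic and numerics; it
does not certify performance on sparse, irregular field data, where
center error and missed seasons dominate.

## Numerical choices and degenerate inputs

* REML: bounded Brent on log θ, tolerance 1e−10; σ²ε floored at the smallest
  positive float when a fit is exact; θ = 0 boundary checked explicitly.
* IRLS: gradient-norm stop at 1e−10, hard stop at |η| > 30 with a separation
  warning; a converged fit with |η| > 15 is also flagged.
* CMP: inversion and normalizer tolerances as above; optimizer is BFGS with
  a numeric gradient (the likelihood is smooth in (β, log ν)).
* MCP: collinear retained points raise a degenerate-geometry error carrying
  area 0, so callers may treat a line as a zero-area range explicitly.
* Outlier rule ties: the comparison is strict (`>`), so equal distances keep
  the fix.
* Bootstrap: refit failures are skipped up to a 10% budget, then the CI is
  refused rather than silently narrowed.

## Problem sizes

The shipped tests and the acceptance script run at the design scale of the
study system: populations of 100 birds × 5 years (~500 transitions),
recovery studies at 2000 birds, repeatability recovery at 200 birds × 4
observations, and a bootstrap-coverage study of 200 simulations × 500
replicates. These sizes give sampling error comfortably inside the asserted
tolerances while keeping the full suite in the minutes range on one CPU.

## Known limitations

* The classifier is threshold-based by design; it does not estimate
  per-bird home ranges from sparse data and cannot express classification
  uncertainty near the boundary.
* Repeatability is defined on log distance, not on the binary decision.
* The CMP regression uses a shared dispersion ν across observations.
* No survival, detection, or habitat processes are modeled in the
  generator, and triangulation error is a free scatter parameter rather
  than a bearing-level error model.
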