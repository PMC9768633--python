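# Methods

This note documents the models and procedures implemented in `deprindex`,
the assumptions behind them, the choices made where the design was
genuinely open, and what the synthetic test bed does and does not
establish about real data.

## Index model

The deprivation score is a composite of nine regional indicators, three
per subdimension (education, employment, income). The pipeline is:

1. **Harmonization** (see below) yields a complete, artefact-free panel
   for 1998–2019 at each indicator's native spatial level (district, or
   GVB for the unemployment rate, employment rate and income tax).
2. **Weighting.** Per dimension, the three indicators are pooled over
   all regions and the years 2001–2019 (earlier years contain imputed
   values and are excluded from the fit to keep imputation from shaping
   the weights), z-standardized on the pooled sample, and decomposed:
   the first eigenvector of the 3×3 correlation matrix, scaled by √η,
   gives loadings λᵢ ∈ [−1, 1]; η = Σλᵢ² is the first component's
   variance. The component is oriented so deprivation-increasing
   indicators (by declared polarity, e.g. the unemployment rate) load
   positively. Second and third eigenvalues are reported as
   one-dimensionality diagnostics, with a warning when the first
   component explains less than 50 % of the dimension variance.
3. **Scoring.** Regression-method factor scores, Σᵢ (λᵢ/η)·zᵢ, computed
   for *all* years 1998–2019 using the standardization constants frozen
   from the pooled fit, so early years are on the fitted scale. Any
   affine-equivalent scoring convention produces the identical final
   index because of the subsequent min-max normalization (tested as an
   invariance property).
4. **Composition.** Dimension scores are min-max normalized to [0, 1]
   within each year at the municipality level, summed (each dimension
   carries weight ⅓), and the sum is normalized again.
5. **Aggregation.** Scores at coarser levels are population-weighted
   means of municipal scores with yearly population weights, then
   renormalized within the target level and year, so every level spans
   [0, 1]. Weighted-mean aggregation is associative: municipality →
   district equals municipality → GVB → district (tested to float
   tolerance). A district → custom-geography projection (e.g. zip-code
   areas) uses the same weighted-mean logic with crosswalk weights.
6. **Quintiles.** Regions are ranked per level and year into five fifths
   over *units* (not population): with n regions the cut counts are
   ⌈nk/5⌉, so n = 401 gives 81/80/80/80/80; tied scores share the lower
   quintile. Quintile 1 is the least deprived fifth; the low/mid/high
   analysis grouping collapses {1}, {2–4}, {5}. Municipalities within
   one GVB share all indicator values and hence their score, so at the
   municipality level tie groups can unbalance the fifths — the ≤1-size
   balance holds at levels with distinct scores.

The GVB-level panel carries a `reduced_resolution` flag: only three of
the nine indicators vary below the district level, so GVB scores carry
more uncertainty than district scores.

## Harmonization

Order of operations: district→GVB broadcast, deflation/log, break
correction, reform correction, East–West correction, carry-forward,
model imputation. Artefact removal precedes imputation so the imputation
model never learns the artefacts. Every applied step is recorded in a
correction ledger (indicator, step, parameters, rows touched) and a
second application of the same step is refused.

* **Broadcast.** Indicators published only at district resolution in
  early years (unemployment and employment rates, 1998–2000) assign the
  district value to every member GVB; within-district GVB variance is
  exactly zero for those years.
* **Deflation + log.** Currency-valued, open-ended indicators (gross
  wage, household income, income tax) become ln(value / deflator). The
  deflator is a per-year user input with a declared base year; the
  default is an identity deflator with a logged warning. Scaling such an
  indicator by a constant (a unit change) shifts the log series
  uniformly and leaves the final index bit-identical.
* **Break correction.** A reporting-procedure changeover shifts the
  level of the two employee-qualification indicators at a known year.
  The shift is the step coefficient from OLS of the indicator on region
  fixed effects, a linear year trend and a post-break dummy (estimated
  by within-region demeaning); pre-break values are raised by the
  estimated shift. Separating step from trend makes the estimator exact
  on noiseless fixtures.
* **Reform correction.** Double graduation cohorts deflate the share of
  school leavers without a certificate in specific state-years. The
  affected (state, year) cells are configuration, not auto-detected —
  the reform calendar is administrative knowledge, and hard-coding
  contested pairs would bake errors into the toolkit. The dip is the
  reform-cell coefficient from a two-way (region and year) fixed-effects
  regression and is subtracted in affected cells only.
* **East–West correction.** The share of employees without professional
  qualification is structurally lower in East German states for
  historical reasons unrelated to present deprivation, producing a
  bimodal distribution. The correction adds the pooled mean difference
  (West minus East, over all region-years; pooled rather than per-year
  as the simpler reading of an "average difference") to East values.
  Bimodality is diagnosed with Sarle's bimodality coefficient
  (BC = (skew²+1)/(excess kurtosis + small-sample term), flag at 0.555,
  the uniform distribution's value); BC was chosen over a dip test as a
  deterministic closed form with no dependency. After correction the
  indicator must correlate with its dimension siblings in the direction
  their polarities imply; a sign violation warns. Which states count as
  "East" is a configurable set — mixed cases like Berlin default to
  West.
* **Carry-forward.** Isolated single-year reporting gaps copy the
  nearest earlier observed year (default 2011 → 2012); both years are
  parameters because the source documentation is ambiguous about the
  target year. Copied cells are flagged as imputed.
* **Random-intercept imputation.** Remaining missing years (mostly
  1998–2003 starts) are predicted from value = μ + β·year + aᵣ with
  region intercepts aᵣ ~ N(0, σₐ²): the slope is the within-region OLS
  estimator, variance components come from method of moments, and the
  region intercepts are empirical-Bayes-shrunk region means. This
  closed form needs no iterative optimiser, is exact in the noiseless
  limit, and its mean absolute error stays within three noise standard
  deviations in simulation. Observed cells are never overwritten;
  imputed cells are flagged.

## Epidemiological linkage

* **Direct age standardization.** rate = 10⁵ · Σₐ wₐ(eventsₐ/popₐ) / Σₐ wₐ
  with the 2013 European Standard Population weights (shipped in-code,
  19 five-year groups: the infant group merged into 0–4 and 90–94/95+
  merged into 90+, summing to 100,000). An age cell with zero population
  and nonzero events is an error; with zero events it is dropped and the
  weights renormalize.
* **Group trajectories.** Standardized rates per low/mid/high deprivation
  group, sex and year; declines reported absolutely and relative to the
  first year.
* **Multilevel Poisson rate ratios.** events ~ Poisson(exp(age effects +
  quintile effects + log population + u_district)), u ~ N(0, σ²),
  quintile 1 as reference, sexes fitted separately. The marginal
  likelihood is integrated with 25-node Gauss–Hermite quadrature and
  maximised with BFGS using analytic gradients, warm-started from the
  corresponding Poisson GLM; Wald intervals come from the numerical
  Hessian. A "second level" realized as a random intercept is the
  simplest structure consistent with district-constant exposure. With
  the random intercept disabled the model is the plain statsmodels GLM,
  for which the single-stratum two-district rate ratio equals the hand
  ratio exactly. Year effects are optional and off by default for
  pooled multi-year tables.
* **Gradient regression.** OLS of a district outcome on the 0–1 index;
  since the index spans [0, 1] the slope is the predicted difference
  between the most and least deprived district; adjusted R² is reported.

## Synthetic data

The generator emulates the real data's statistical anatomy at a reduced
default scale (500 municipalities, 200 GVB, 50 districts, 12 planning
regions, 5 NUTS-2, 10 states of which 3 "East"), chosen so the full
generate→harmonize→weight→index pipeline runs in a few seconds; full
real-world sizes are reachable through the count parameters.

Three latent dimension factors evolve per district as AR(1) processes
(ρ = 0.9, unit marginal variance) — the pooled PCA uses between-year
variation, so the synthetic data must have some — sharing a common
component calibrated so the pairwise factor correlations hit the
configured targets (0.66/0.52/0.69 by default). Within a dimension the
indicators are z = λᵢ·f + Sᵢ·ε with a **shared** two-dimensional
residual ε and a mixing matrix S solved so that the population
correlation matrix λλᵀ + SSᵀ is a correlation matrix whose *first
principal component has loadings exactly λ*. The naive construction
(independent noise per indicator) biases the first-PC loadings upward by
as much as 0.17 for the weakest loadings, which would make tight
recovery impossible by construction. For the published loading patterns
the residual eigenvalues land at 0.18–0.79, below the first-component
eigenvalues of 1.57–2.05. With the noise scale at zero and artefacts
off, every indicator is an exact affine image of its latent factor.

Injected pathologies mirror the real calendar: availability windows per
indicator (education employee shares from 2001 with a missing 2012;
wage/income from 2000; debtor quota from 2004), a level break on the two
employee-qualification indicators, reform dips in configured
state-years, an East offset (−5 points) on the qualification indicator,
and district-only resolution of the employment-rate indicators before
2001. GVB-native indicators add within-district factor variation
(sd 0.3) on top of the district factor.

Health outcomes are Poisson counts per district, year, sex and 5-year
age group: population split by a fixed age profile, exponential age
gradient in the baseline rate, male excess 1.5, a yearly proportional
decline (3 %) with an optional extra decline per unit of the index, a
log-normal district frailty (sd 0.05), and a log-linear deprivation
effect whose default targets a 1.46 top-versus-bottom-quintile rate
ratio over the typical 0.5 quintile-mean gap of the 0–1 index.

All randomness flows through one named `numpy.random.Generator` per
artefact family, seeded from the config seed; equal seeds give
bit-identical output.

### What the synthetic bed does not establish

The generator produces Gaussian, stationary, linearly-mixed indicators
with a single break and clean mixture offsets. Real indicator panels
have skewed marginals, boundary effects (shares near 0), spatially
correlated shocks, drifting availability and territorial reforms. The
passing recovery experiments therefore validate the *estimators'
correctness under their stated models*, not their robustness to real
INKAR data. Likewise, published real-data associations
(life-expectancy gaps of 6.0/3.2 years, cancer rate ratios 1.46/1.23,
cardiovascular trajectories) depend on external registry data and are
used here only as magnitudes for programmed-recovery experiments.

## Numerical choices

* PCA on the correlation (not covariance) matrix: indicators have
  incommensurable units, and loadings in [−1, 1] are interpretable as
  correlations.
* Pooled standardization is global over region-years, not per-year:
  per-year z-scoring would erase the between-year variation the pooled
  design is meant to use.
* Pooled PCA observations are unweighted region-years (no population
  weighting).
* Min-max normalization requires ≥2 distinct values per year; constant
  years are an error, not silently 0.
* Quintile tie-break: ties share the lower quintile; deterministic for
  a given input.
* Loading-recovery experiments run with sub-district factor variation
  switched off, because with it the "true" first-PC loading is no
  longer the generating λ; ~5,000 pooled observations (263 districts ×
  19 pool years) bound the worst-case recovery error near 0.047.
* Gauss–Hermite node count 25; BFGS convergence is accepted when the
  reported optimum has a gradient numerically at zero relative to the
  deviance, which BFGS otherwise reports as "precision loss".
* Problem sizes in tests and the acceptance script (50-district default
  replica, 20 recovery replicates, 4-year outcome windows) are chosen to
  keep the whole validation suite in the tens of seconds while leaving
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The imputation model assumes a common linear trend; indicators with
  region-specific trends are extrapolated with shrunk intercepts only.
* The East–West correction equalizes pooled means; if the East–West gap
  trended over time, a per-year correction would differ.
* The Poisson GLMM uses a single random intercept; nested or crossed
  structures (e.g. year within district) are out of scope.
* Quintiles are unit-weighted; population-weighted fifths are a
  different, deliberately unimplemented variant.
* No geometry: shapefiles, map rendering and historical boundary
  changes are out of scope (inputs are assumed harmonized to one
  territorial status).
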