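# Methods

## The design and the estimand

The package implements a time-stratified case-crossover analysis for
acute exposure effects. Each death contributes one stratum: the case
day (date of death) and its referent days — all other days in the same
calendar month and year sharing the case day's day of week. By the
calendar, every stratum has 3 or 4 referents, and the referent relation
is symmetric (if d2 is a referent of d1, d1 is a referent of d2; the
same-weekday days of a month partition it into referent classes).
Matching on weekday-within-month controls day-of-week effects,
seasonality and long-term trends by design; time-invariant individual
characteristics cancel because each subject is their own control.
"Location" matching is automatic: a death's referent rows use the same
locality's exposure series.

The conditional-logistic likelihood for stratum *i* with covariate rows
x and one case is

    L_i(β) = exp(x_case'β) / Σ_rows exp(x_row'β),

a stratified-Cox partial likelihood; stratum intercepts cancel. The
covariates are seven linear distributed-lag PM2.5 terms (lags 0–6,
µg/m³) plus a temperature adjustment. The target summaries are the
cumulative log-odds sums over lags 0–1 (lag01) and 0–6 (lag06),
reported as percent increase per 10 µg/m³, 100·(exp(10·β)−1).

When several deaths share a locality and month the product over strata
is a composite likelihood: scores remain unbiased (each stratum's
conditional probability is correctly specified), but model-based
standard errors ignore the shared exposure. In the bench scenarios the
resulting miscalibration is small (null coverage ≈ 0.93–0.95; the
linearity test rejects at ≈ 0.06–0.08 at nominal 0.05); the calibration
checks measure it rather than hide it.

## Numerical details

- **Likelihood.** Computed per stratum with max-subtraction before
  exponentiation; gradient and Hessian are analytic and evaluated in
  the same vectorised pass (`np.add.reduceat` over contiguous stratum
  blocks).
- **Optimiser.** Newton–Raphson from β = 0 with step-halving (max 50
  halvings); convergence when max |gradient| < 1e-8 or the relative
  log-likelihood change < 1e-10. The covariance is the inverse negative
  Hessian at the optimum. Columns with no within-stratum variation are
  non-informative; they are excluded from the optimisation and reported
  (coefficient 0, variance NaN). A coefficient norm above 30 log-odds
  flags possible separation and the fit is marked non-converged.
  Singular Hessians raise an error naming the most collinear columns.
- **Temperature basis.** Quadratic B-spline with df = 4: two interior
  knots equally spaced in the observed predictor range (range computed
  from the pooled case + referent values of the analysis at hand), with
  clamped end knots, evaluated by the Cox–de Boor recursion
  (scipy.interpolate.BSpline). The full df+1-column basis is a
  partition of unity; because strata absorb constants, one column is
  dropped and df columns enter the design. By default the basis is
  taken of the mean temperature over lags 0–6 — one smooth covering the
  same window as the exposure lags; a per-lag-basis option exists. The
  default temperature truth in the generator is exactly quadratic, so
  the df-4 quadratic spline can represent it without approximation
  error; the confounding-control check verifies adjusted bias < 20% of
  unadjusted bias under a strongly confounded scenario.
- **Linearity screen.** A fixed-df likelihood-ratio test: each linear
  lag term is replaced by a quadratic B-spline expansion (df = 3 per
  lag, i.e. 2 added columns, 14 added df in total). The spline span
  plus stratum constants contains every linear function, so the models
  are nested and the statistic is non-negative with a chi-squared
  reference. A penalised thin-plate GAM with data-driven smoothing is a
  different estimator class and deliberately out of scope; the fixed-df
  LRT answers the same nesting question with an exact null reference.
- **Effect modification.** Two subgroup fits are contrasted on the
  log-odds scale: diff = E1 − E2, 95% CI = diff ± 1.96·√(se1² + se2²),
  flagged when the CI excludes 0. Subgroup dichotomies: age 18–64 vs
  ≥ 65 (65 itself is elderly); male/female; no education vs basic or
  more; social-security affiliation vs none; employed vs not employed
  ('unspecified' levels dropped; employment analyses restricted to a
  configurable sub-period, default 2013–2019, reflecting an
  occupational-coding change).
- **No multiplicity correction** is applied; results tables report raw
  Wald 95% CIs.

## Exposure assignment

Cells are half-open unit squares [x, x+1)×[y, y+1), so every in-domain
point has exactly one containing cell. Urban polygons get
Σ v_c·w_c / Σ w_c with w_c = population_c × exact intersection-area
fraction; weights are frozen at a single census snapshot. A
locality-day with any missing contributing cell is flagged incomplete
and the assigned value left missing — weights are never renormalised
over the observed cells; incomplete days are excluded later by the
complete-lag-history rule. This is the conservative reading of a
complete-exposure-history exclusion; renormalisation would silently
change the spatial support of the average.

The study window starts one month after the exposure record begins
(first eligible case day = first day of the second exposure month), so
every case and referent day — including referents that precede the case
within its month — carries a complete 7-day lag history.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not any particular city:

- **Geography.** Urban localities are 2×2-cell rectangles with
  lognormal positive population weights per cell; rural localities are
  single points inside otherwise free cells. Defaults are 6 + 6
  localities on an 8×8 grid; the geography scales to hundreds of
  localities when asked.
- **Exposure surfaces.** value = mean + seasonal sinusoid + static
  spatially smoothed field + AR(1) temporal noise whose innovations are
  themselves spatially smoothed (daily surfaces co-move across nearby
  cells, as real pollution fields do — and without this, polygon
  averaging would artificially destroy day-to-day exposure variance).
  PM2.5 is floored at 0 to respect its physical support; PM and
  temperature innovations share a configurable fraction (cross_corr).
  Default marginal moments target a polluted-megacity regime: PM2.5
  mean 24.6, SD ≈ 10.8 µg/m³; temperature mean 16.6 °C, SD ≈ 2.5 °C.
  The true spatio-temporal covariance of real exposure surfaces is not
  published at this resolution; these defaults are chosen for
  testability, not fidelity.
- **Mortality.** Locality-day counts are Poisson with log-rate =
  log(baseline) + weekday effect + month-level seasonal and trend terms
  + Σ_l β_l·PM(t−l) + f(mean temperature over lags 0–6), centred so the
  realised rate stays near the configured baseline. The weekday and
  month-level terms are injected deliberately: they are exactly the
  structure the time-stratified design must absorb, so the
  conditional-logistic estimand equals the injected β vector. (A
  within-month smooth trend would not be absorbed and would shift the
  estimand; the generator therefore keeps confounders stratum-constant
  on purpose.) ICD-10 codes are stamped independently of exposure from
  a configurable mix, with an option to give one cause its own lag
  coefficients; demographics come from fixed categorical mixes
  (elderly share 0.627, male 0.508, etc.). An optional quadratic lag-0
  PM term provides a nonlinear truth for power checks of the linearity
  screen.
- **What passing does not show.** The generator has no holidays, no
  humidity, no exposure measurement error, no garbage-code
  misclassification and no population mobility; recovery and
  calibration results demonstrate correctness of the estimator under
  its assumed sampling model, not robustness to those real-data
  features.

## Bench problem sizes

All verification scenarios run on one CPU:

- Parameter recovery: 36 localities, six years, ~30,000 deaths per
  seed, 20 seeds; the exposure process uses AR(1) 0.85 and innovation
  SD 12 so each run's cumulative-effect SE is ≈ 0.8 percentage points,
  giving the 20-seed mean a ≈ 0.18-point standard error against the
  ±0.5-point recovery margin.
- Null calibration: 200 replicates of a 12-locality, 17-month,
  ~1,500-death scenario.
- Linearity test size: 200 replicates with ≈ 0.07 deaths per
  locality-day (little stratum duplication, which would otherwise
  inflate the test); power: 10 replicates with a strong quadratic
  term at ~5,000 deaths.
- Confounding control: 6 seeds of a 3-year scenario with zero PM truth,
  monotone-quadratic temperature effect and cross_corr 0.7.
- Effect-modification power: two ~40,000-death studies per seed with
  truths 0% and 4% per 10 µg/m³.

## Known limitations

- Model-based (independence) standard errors; no cluster-robust or
  bootstrap variance for shared-exposure duplication.
- Single planar CRS; no reprojection, no temporal weight interpolation,
  no gap imputation.
- Time-stratified referents only (no bidirectional/symmetric schemes).
- No penalised GAM estimation, no Bayesian variants, no
  mortality-displacement (harvesting) analysis.
- ICD-10 only, classified at three-character resolution; no
  garbage-code redistribution.
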