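# lagcrossover

Time-stratified case-crossover analysis of short-term fine-particulate
(PM2.5) exposure and cause-specific mortality, with distributed-lag
conditional-logistic inference and a ground-truth synthetic-data
generator.

The package is for environmental epidemiologists and biostatisticians
who want a tested, reusable implementation of the full analysis chain
used in daily air-pollution mortality studies:

1. **Exposure assignment** — daily 1×1-km gridded PM2.5 and temperature
   surfaces assigned to sub-municipal localities: population-weighted
   polygon aggregation for urban localities, containing-cell lookup for
   rural point localities.
2. **Cohort construction** — non-accidental adult deaths (age ≥ 18),
   external-cause blocks V–Y excluded except intentional self-harm and
   assault (X60–Y09), mapped to mutually exclusive broad-category
   (organ-system) and cause-specific ICD-10 outcome groups.
3. **Case-crossover design** — each death is its own stratum: the case
   day plus every other same-weekday day in the same month and year
   (3–4 referents), each row carrying a complete 7-day exposure history
   (lags 0–6); strata with any missing lag value are dropped.
4. **Inference** — the conditional-logistic model

   logit P(case | x) = α_i + Σ_l β_l PM_lag_l + f(temperature),

   where the stratum intercepts α_i cancel from the conditional
   likelihood L(β) = Π_i exp(x_case'β) / Σ_rows exp(x_row'β), maximised
   by Newton–Raphson. Temperature enters as a quadratic B-spline (4 df,
   equally spaced knots) of the lag 0–6 mean. Effects are reported as
   the percent increase in the odds of death per 10 µg/m³ PM2.5,
   100·(exp(10·β)−1), with Wald 95% CIs; cumulative windows lag01 and
   lag06 sum the lag coefficients with delta-method standard errors.
   Nonlinearity of the concentration–response is screened by a
   spline-vs-linear likelihood-ratio test; effect modification between
   subgroups by the contrast (E1−E2) ± 1.96·√(σ1²+σ2²) on the log-odds
   scale.
5. **Synthetic data** — geography (urban cell-block polygons with
   population weights, rural points), seasonal + spatially correlated +
   AR(1) exposure surfaces, and Poisson mortality with known lag-specific
   effects and deliberately injected weekday/month-level confounding —
   so every stage is verifiable against ground truth without
   confidential registry data.

## Worked example

`python examples/01_simulate_and_fit.py` simulates a small study whose
true one-week cumulative effect is 2% per 10 µg/m³ and runs the whole
pipeline:

```
simulated deaths: 6365
ground truth lag06: 2.00% per 10 ug/m3
strata fitted: 6169 (dropped 0; converged=True)
lag01: -0.03% per 10 ug/m3 (95% CI -4.69 to +4.85)
lag06: +0.52% per 10 ug/m3 (95% CI -5.40 to +6.82)
```

The lag06 line is the estimated one-week cumulative percent increase in
the odds of death per 10 µg/m³ higher PM2.5; at this small sample size
the interval is wide and covers the 2% truth. The other examples show
referent selection, ICD-10 classification, exposure assignment,
effect-modification contrasts and the linearity screen. A thin CLI
wraps the pipeline: `lagcrossover run --config run.yaml --out results/`
and `lagcrossover simulate --out data/`.

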