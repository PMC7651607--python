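# drmmrm

Simulation and estimation toolkit for **dose-response mixed models for
repeated measures (DR-MMRM)** — a way to analyze longitudinal
dose-finding trials with a highly variable endpoint by combining the
robustness of MMRM with the borrowing-of-strength of an Emax
dose-response model.

The motivating setting is phase-2 dose finding in chronic kidney
disease, where the endpoint is log urinary albumin-to-creatinine ratio
(UACR): a fast-responding but very noisy proteinuria biomarker. The
package simulates complete 16-week trials of log-scale change from
baseline (∆UACR) and compares three analyses of the placebo-adjusted
effect ∆∆UACR:

* **MMRM** — saturated arm × visit cell means with an AR(1) residual
  covariance. Assumption-free in the mean, unbiased, but one parameter
  per cell and no interpolation between doses.
* **DR-EOS** — a three-parameter Emax model
  `y = Plc + Emax · d/(ED50 + d)` fitted by bounded nonlinear least
  squares to the end-of-study visit only.
* **DR-MMRM** — the method of interest: per-visit placebo and Emax
  parameters tied together by a *single* ED50 shared across visits,
  with AR(1) residual covariance. Fitted once per dose arm in the
  reference-dose parameterization

  `y = Plc_t + E_dose,t · [d/(ED50+d)] · [(ED50+dose_m)/dose_m]`,

  which collapses to `Plc_t + E_dose,t` at `d = dose_m`, so each arm's
  per-visit effect and standard error are read directly off its own fit
  while all parameterizations share one likelihood optimum.

Trials are simulated as
`y_it = Emax(ED50)·f(t)·d/(ED50+d) + η_i + ε_it` with subject
heterogeneity `η_i ~ N(0, ω²)`, AR(1) residuals
(`σ`, lag-1 correlation `ρ` per visit), ω = 0.3716, σ = 0.50,
ρ = 0.226, and Emax anchored so the 100 mg arm reaches a 40% UACR
reduction (log 0.6) at full effect. The Monte-Carlo engine sweeps
ED50 ∈ {2,…,128} mg × {direct, exponential, linear} time-courses and
reports bias, relative bias, SD and RMSE = √(sd² + bias²) per method.

## Worked example

`python examples/02_fit_three_methods.py` simulates one trial
(ED50 = 32 mg, linear time-course) and fits all three methods:

```
        ddUACR                    se
method  DR-EOS DR-MMRM   MMRM DR-EOS DR-MMRM   MMRM
dose_mg
3.0     -0.116  -0.078 -0.056  0.064   0.041  0.142
10.0    -0.288  -0.215 -0.209  0.116   0.090  0.142
30.0    -0.501  -0.432 -0.554  0.119   0.116  0.142
100.0   -0.675  -0.669 -0.608  0.117   0.123  0.142

truth at week 16: {3: -0.058, 10: -0.161, 30: -0.326, 100: -0.511}

ED50 estimates — DR-EOS: 17.6 mg, DR-MMRM: 30.7 mg (true 32 mg)
```

A ∆∆UACR of −0.51 log(mg/g) is a 40% reduction in UACR. The MMRM
standard error (0.142) sits at the theoretical
√(ω²+σ²)·√(2/39) ≈ 0.141 for every dose; the dose-response methods are
markedly more precise at the lower doses because they share information
across arms (and, for DR-MMRM, across the nine visits).

Other examples: `01_simulate_a_trial.py` (simulator and its variance
structure), `03_operating_characteristics.py` (a small Monte-Carlo
study: bias/SD/RMSE per cell and ED50 percentile summaries),
`04_design_calculations.py` (n = 39 per arm from the 95%-power
requirement, theoretical RMSE 0.141, ±1.75% unbiasedness band).

## Command line

The same pipeline is scriptable:

```sh
drmmrm simulate --config config.yaml            # write trial CSVs
drmmrm fit trial.csv --method DR-MMRM           # fit one method
drmmrm study --reps 1000 --arm-config 4dose \
       --seed 1 --out study_out --resume        # full study, resumable
```

A full-scale run (21 scenarios × 1000 replicates × 3 methods) is an
overnight job on one CPU; per-scenario checkpoints make it resumable.

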