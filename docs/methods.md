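# Methods

## The problem

Dose-finding trials with a noisy longitudinal endpoint face a trade-off.
A saturated MMRM (one mean parameter per treatment arm × visit, with a
within-subject residual covariance) makes almost no assumptions and is
unbiased under complete or missing-at-random data, but it ignores the
ordering of doses and so pays in precision, especially for the lower
arms. A dose-response model fitted only to end-of-study data borrows
strength across arms but throws away every earlier visit. DR-MMRM keeps
the per-visit placebo and effect structure of MMRM while constraining
the dose dimension to an Emax shape with one ED50 shared across visits,
borrowing strength in both directions.

## Generative model

Trials are complete, balanced panels of log-scale change from baseline
in UACR (∆UACR) at nine post-baseline visits (weeks 2, 4, 6, 8, 10, 12,
14, 15, 16):

    y_it = effect(d_i, t) + η_i + ε_it
    effect(d, t) = Emax(ED50) · f_tc(t) · d / (ED50 + d)
    Emax(ED50)   = log(0.6) · (100 + ED50) / 100
    η_i ~ N(0, ω²),   ε_i ~ N(0, σ² R(ρ)),   R_jk = ρ^|j−k|

with ω = 0.3716, σ = 0.50 log(mg/g), ρ = 0.226 per visit position (so
the closely spaced week-14/15/16 visits correlate like the 2-week-spaced
ones). The Emax anchoring makes the 100 mg arm reach exactly a 40%
UACR reduction at full effect for every ED50. Time-courses: direct
(full effect from the first visit), exponential
(1 − 2^(−t/1.75), half-life 1.75 weeks), linear (t/16, capped at 1
beyond week 16, which the schedule never reaches).

Design defaults are the study conditions: 39 subjects per arm (the
normal-approximation two-sample sample size for 95% power to detect the
40% reduction at α = 0.05 with SD √(ω²+σ²): 38.65, rounded up — the
exact noncentral-t calculation would give 40, and the empirical t-test
power at n = 39 is 94.7%), one placebo arm plus active doses
(3), 10, 30, 100 mg, ED50 grid {2, 4, 8, 16, 32, 64, 128} mg, 1000
replicates per scenario at full scale.

Two modelling choices deserve note. First, ∆UACR is simulated directly
with a subject-level intercept of SD ω rather than by simulating
absolute values and differencing: this is the only generative reading
under which both the n = 39 power computation and the theoretical
end-of-study precision √(ω²+σ²)/√n·√2 ≈ 0.141 hold simultaneously, and
both are reproduced empirically by the simulator tests. Second, the
placebo response is exactly zero on the change scale; every reported
quantity is placebo-adjusted, so a common placebo drift would cancel
anyway. The absolute-scale export (baseline mean 5.63 log(mg/g))
exists only for round-trip realism; baseline level never enters the
results.

## Estimation

All three estimators share one numerical core: Gaussian generalized
least squares under a per-subject AR(1) working covariance, with the
linear parameters and the scale profiled out in closed form (the AR(1)
inverse and determinant are closed-form tridiagonal expressions, and
subjects sharing a design block are pooled into per-group sufficient
statistics). What remains is a bounded search over the correlation
(arctanh scale, |ρ| ≤ 0.999) and, for the dose-response MMRM, the ED50
(log scale, bounds [0.01, 10⁴] mg, multi-start from
{1, 10, 30, 100, 300} mg; estimates within 10⁻³ relative distance of a
bound are flagged).

* MMRM: saturated cell means. On balanced complete data the point
  estimates equal raw cell means for any working correlation (a tested
  invariant); the AR(1) fit supplies model-based standard errors. REML
  is the default criterion, ML an option; on balanced data the choice
  does not move the point estimates.
* DR-EOS: bounded nonlinear least squares of
  `Plc + Emax·d/(ED50+d)` on last-visit data, multi-start over ED50,
  delta-method SEs from the Jacobian-based parameter covariance.
* DR-MMRM: fitted once per active arm in the reference-dose
  parameterization; each arm's per-visit effect E_dose,t and SE are kept
  from its own fit, ED50 and the back-calculated per-visit Emax from the
  best-likelihood converged parameterization. **Criterion: maximum
  likelihood, not REML.** A restricted likelihood is not invariant to
  the ED50-dependent rescaling of the drug-effect columns across
  reference-dose parameterizations (its log|X'V⁻¹X| term changes), so
  under REML the parameterizations of one trial would disagree; profiled
  ML depends only on the column span, making all parameterizations share
  one optimum exactly — which is also what nonlinear GLS software fits.
  Effect SEs come from the joint Gauss-Newton information including the
  ED50 direction, so ED50 uncertainty is propagated; the ED50 SE itself
  is a numeric profiled-curvature convenience output, not a study
  endpoint. A parameterization counts as converged when the outer
  optimizer succeeds and the inner solve is positive definite; a trial
  is a complete failure only when every parameterization fails.

The working covariance is AR(1) only, without a random-intercept term,
even though the truth adds ω²: the AR(1) model absorbs the intercept as
a higher apparent correlation (marginal lag-1 ≈ 0.50 at the study
conditions). Point estimates stay unbiased on the saturated balanced
design; any SE miscalibration is part of what the study measures.
Confidence intervals use the normal 1.96 quantile (n = 39 per arm makes
t-vs-z negligible).

## Metrics

Per grid cell (time-course × ED50 × dose), on the last visit: bias
(Monte-Carlo mean minus truth, log scale), relative bias as % of the
maximal effect |log 0.6|, SD across replicates, RMSE = √(sd² + bias²).
The unbiasedness band is ±2 SD of an unbiased method's Monte-Carlo mean
relative bias: 100·2·√(ω²+σ²)√(2/n)/√reps/|log 0.6| — ±1.75% at 1000
replicates — and is always recomputed for the replicate count actually
used, since it scales as 1/√reps. ED50 and end-of-study Emax are
summarized by medians and 2.5/97.5 percentiles; means are meaningless
because a minority of fits sit on the upper ED50 bound whenever the
true ED50 approaches or exceeds the top dose.

## Problem sizes and what the tests show

The test suite runs the study at desk scale: the MMRM unbiasedness
audit on the full 4-dose grid at 100 replicates/scenario (band
recomputed for 100), and all three methods at 50 replicates/scenario
for the RMSE and bias checks. At 50 replicates the per-cell RMSE and
bias estimates carry visible Monte-Carlo noise, so cell-wise claims are
tested as confidence-bound statements: worst-case |relative bias| is
checked net of a 3-SE allowance per cell, and the cell-wise RMSE
ordering (DR-MMRM ≤ MMRM) net of a paired-jackknife 3-SE allowance with
strict ordering required in ≥95% of cells. Full-scale behaviour (1000
replicates, hours on one CPU) is reachable through `run_study` or
`drmmrm study --reps 1000`.

Passing tests show the estimators are correct for data generated by
this model: Gaussian errors, no dropout, a non-sigmoid Emax truth
matching the fitted family, visits exactly on schedule. They do not
show robustness to informative dropout, model misspecification (e.g. a
sigmoidal true dose-response), skewed errors, or off-schedule sampling
— all outside this package's scope.

## Numerical choices

* AR(1) inverse/determinant in closed form; dense-likelihood equality is
  enforced against a brute-force multivariate-normal oracle in tests.
* Outer searches: bounded Brent in arctanh ρ (MMRM), L-BFGS-B over
  (log ED50, arctanh ρ) with the empirical lag-1 autocorrelation as the
  ρ start (DR-MMRM), trust-region-reflective NLS (DR-EOS).
* Degenerate inputs: single-visit panels fix ρ = 0 with a message;
  rank-deficient designs raise a singular-design error; flat responses
  yield Emax ≈ 0 rather than failure.
* Seeding: master seed → per-scenario SeedSequence spawn → per-replicate
  spawn; any single trial is re-simulable in isolation and every run is
  bit-reproducible, including across checkpoint resume (CSV round trips
  use full precision and exact-rounding parsing).
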