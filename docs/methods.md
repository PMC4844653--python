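# Methods

## Tumour-size kinetic model

Tumour burden of patient *i* at time *t* (days since randomisation) is

    TS_i(t) = BASE_i · exp(−SR_i · t) + PR_i · t

with BASE_i the baseline burden (mm), SR_i the shrinkage rate constant
(1/day) of the drug-sensitive fraction and PR_i the linear regrowth rate
(mm/day) of the resistant fraction.  Observations are lognormal around the
model curve (residual log-SD σ), and the individual parameters are
lognormal across patients: log BASE_i ~ Normal(θ_BASE, ω_BASE), etc.  Time
is handled in **days** inside this module — the default population values
(θ = 4.58/−6.78/−3.17, ω = 0.648/1.32/0.835, σ = 0.150) reproduce typical
week-2 to week-10 shrinkage fractions of 1.0–4.7 % only under per-day
rates — while scan schedules, survival times and all reporting use weeks,
with explicit conversion (×7) at module boundaries.

Only *evaluable* patients (a baseline scan and at least one on-treatment
scan) enter the fit.  Priors are weakly informative and overridable:
Normal(0, 10) on each θ, half-Normal(0, 5) on each ω and on σ.

### Posterior sampling

The posterior is explored with a blocked Metropolis-within-Gibbs sampler
designed for this model's structure:

* individual log-parameters are conditionally independent across patients
  given the population parameters, so the per-patient random-walk
  Metropolis updates of log BASE, log SR and log PR are vectorised over the
  whole cohort, with per-patient step sizes adapted toward a 44 %
  acceptance rate during warm-up (Robbins–Monro, frozen afterwards);
* an additional joint move perturbs (log SR, log PR) in opposite
  directions — for sparsely scanned patients the likelihood is nearly flat
  along this trade-off, and the extra direction removes the slow mixing it
  otherwise causes;
* population log-means θ have conjugate normal Gibbs updates; ω's and σ use
  adaptive log-scale Metropolis steps.

Defaults are 4 chains × 500 retained draws after warm-up, thinned (10–16×)
so retained draws are close to independent; a cohort of 150 patients fits
in well under a minute.  Convergence is monitored by split-R-hat on every
sampled quantity (population and individual), with the acceptance rule
*all R-hat < 1.1*; `check_convergence` reports offenders rather than
failing silently.

### Shrinkage metrics

PTR(w) = 1 − TS_i(7w)/BASE_i, the model-predicted fractional reduction at
week w ∈ {2,…,10}, is computed from **posterior means** of the individual
parameters (full-posterior propagation is available but off by default;
ignoring individual-parameter uncertainty can bias downstream covariate
tests, a known limitation).  PTR is stored as a fraction, positive =
shrinkage; a "1 unit" effect in the survival models therefore means 100
percentage points of baseline burden.  PTR_max is the best *observed*
fractional reduction within 12 weeks; it is NaN (not 0) when no in-window
on-treatment scan exists.

## Accelerated-failure-time survival models

Survival time T (weeks, death from disease; censored at the last visit)
follows lognormal(µ, σ) or Weibull(α, λ) with covariates on the location:

* Weibull: λ = exp(θ₀ + Σ θ_x·x_c) — log-linear, so the acceleration
  factor (ratio of median survival times) is exactly exp(θ_x·Δ);
* lognormal: µ = exp(θ₀) + Σ θ_x·x_c by default.  The linear-in-µ form is
  deliberate: it makes AF = exp(θ_x·Δ) exact for the lognormal too and
  makes exp(exp(θ₀)) the typical median, which is how the reference
  coefficient set reproduces its own printed acceleration factors and the
  ~33-week cohort median.  The fully log-linear µ is available via
  `log_linear=True`; with limited data the two are practically
  indistinguishable, and the choice cannot be settled from fit quality
  alone.

Continuous covariates are centred at the sample median (PTR metrics,
already small fractions, are uncentred).  Internally the sampler works on a
standardised covariate scale (coefficients are transformed back per unit
afterwards) — this keeps the posterior geometry well-conditioned regardless
of units.  Priors: Normal(0, 10) on θ's, half-Normal(0, 5) on σ and α.
Sampling uses an adaptive random-walk Metropolis with Haario covariance
adaptation, preconditioned by a Laplace approximation (BFGS mode and
inverse Hessian); 4 chains × 500 thinned draws, same R-hat < 1.1 rule.

Model comparison uses PSIS-LOO (arviz) on the per-draw per-record censored
log-likelihood; forward covariate selection adds the candidate with the
largest elpd gain, keeping it only when the gain is positive and the 95 %
credible interval of its coefficient excludes zero.  Population survival
curves average analytic per-patient survivor functions over the cohort for
1000 posterior parameter sets (pointwise median and 2.5/97.5 % band,
0–104 weeks in 1-week steps).

## Cox modelling and screening

Breslow tie-handling is used everywhere (ties are rare at week resolution).
Coefficients and covariances come from lifelines; the Breslow baseline
cumulative hazard, centred at the covariate means, is computed in-package
so that S(t|x) = exp(−H₀(t))·exp((x−x̄)β) is fully explicit.  Backward
deletion drops the largest Wald p ≥ 0.05 per step.  PH diagnostics per
variable: (a) Wald test of a linear variable×time interaction in a genuine
time-varying Cox refit (episode splitting at event times), and (b) the
scaled-Schoenfeld zero-slope score test on untransformed time (identity
transform; rank/KM transforms would be alternatives).  Bootstrap CIs are
percentile intervals over patient-level resamples (zero-event resamples
redrawn and logged).  Discrimination is Harrell's c corrected for optimism:
mean over bootstrap fits of (c on the resample − c of that fit on the
original data), subtracted from the apparent c.

Screening: variables with ≥ 30 % missingness are dropped; the rest are
multiply imputed (m = 5) by stochastic regression on the complete columns
plus the event indicator — a deliberate simplification of full chained
equations; ALP, CA19-9 and NEUT are log-transformed (heavily right-skewed);
continuous variables are standardised (sample SD).  The L1 penalty path of
a Cox model (scikit-survival coordinate descent) is cross-validated by
k-fold (k = 10) partial-likelihood deviance of the held-out fold, the
penalty chosen as the CV minimum (not the 1-SE rule) subject to at most 10
active variables; with multiple imputations, variables selected in a
majority of completed tables are retained.  How multiply-imputed selections
should be pooled is genuinely open; the majority rule is this package's
choice.

## Validation

Kaplan–Meier with Greenwood variance and log-transformed 95 % CI.  The
time-dependent AUROC at horizon t uses death-by-t as cases and survival
past t as controls, Mann–Whitney with half-weight ties; patients censored
before t have undefined status and are excluded by default (an IPCW-
weighted variant is available for sensitivity analysis).  Horizons 3/6/9/12
months map to 13/26/39/52 weeks.  The integrated AUROC averages AUROC(t)
over observed event times with weights ∝ 2·f̂(t)·Ŝ(t) from the KM estimate
(a uniform-weight mean is available).  Bootstrap CIs are patient-level
percentile intervals.

## Synthetic cohorts

The generator emulates: lognormal individual kinetics around the population
defaults above; scans at week 0 and every 8 weeks to 69 weeks, truncated at
each patient's observed survival time, with multiplicative lognormal noise;
baseline covariates with realistic medians/ranges (ALB 41 G/l, BSA 1.78 m²,
NEUT 5.75 G/l, TS0 ≈ 100 mm, ECOG 1–2 in 63 %, …), clipped to physiologic
ranges; death times from a lognormal AFT truth (θ₀ = 1.25, θ_TS0 = −0.001
/mm, θ_PTRwk2 = 1.07 per fraction, θ_ALB = 0.0079 per G/l, σ = 0.544)
linked to the patient's true week-2 shrinkage; administrative censoring at
69 weeks.  Optional knobs exercise edge paths: a small probability of
patients with no on-treatment scan (evaluability filter), and MCAR
missingness masks per covariate (imputation).

What it does **not** emulate: staggered accrual (so the censoring fraction
is lower than in a trial where many patients are alive at cut-off),
informative dropout, second-line therapy, and non-cancer deaths.  Passing
recovery tests therefore show the estimators are correct under the stated
generating laws, not that real trial data satisfy those laws.  Under the
default truth the covariate effects are weak — held-out AUROC lands around
0.5–0.7 depending on horizon — which mirrors the modest discrimination
this class of models achieves in practice; power-style tests use explicitly
strengthened effects.

## Numerical choices and problem sizes

* Warm-up adaptation is frozen before retained draws, so chains target the
  exact posterior; thinning (4–16×) keeps the 4 × 500 retained draws close
  to independent for the R-hat rule.
* Kinetic-fit initial values are data-driven (baseline scan) plus generic
  per-day rate scales; chains are jittered per seed.
* Degenerate inputs: zero variability (ω = σ = 0) and zero rates are
  accepted by the simulator (exact typical-curve limit); fitted parameters
  are always strictly positive.  Lognormal AFT locations µ ≤ 0 are treated
  as errors at evaluation time and as rejected proposals during sampling.
* Test-suite problem sizes are chosen to keep the full suite around a few
  minutes: recovery at n = 150 (kinetics) and n = 300 (AFT), 10 replicate
  cohorts of n = 40 for interval coverage, 50 replicates for error-rate
  levels, bootstrap B = 100–200 in tests (B = 1000 remains the analysis
  default).

## Known limitations

* The Metropolis-based samplers mix more slowly than gradient-based HMC
  would on stiffer posteriors; the thinning defaults compensate at these
  problem sizes but would need revisiting for much larger cohorts.
* Posterior-mean PTR understates individual uncertainty (see above).
* The integrated-AUROC weighting and the treatment of patients censored
  before the horizon are conventions; both have switchable alternatives.
* Log-logistic and generalised-gamma AFT distributions, stratified or
  time-varying-covariate Cox models, and shrinkage-prior variable selection
  are out of scope.
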