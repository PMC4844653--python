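# tgisurv

Survival prediction for metastatic pancreatic cancer from longitudinal
tumour-size data.

Patients on palliative gemcitabine chemotherapy have RECIST tumour burden
(sum of longest target-lesion diameters, mm) measured every 8 weeks, a
panel of baseline clinical covariates, and a censored survival outcome.
`tgisurv` implements, tests, and compares the two standard modelling routes
from these data to a per-patient mortality risk:

* **Parametric route (PAR).** A three-stage hierarchical Bayesian model of
  the tumour-size time course,

  ```
  TS_i(t) = BASE_i · exp(−SR_i · t) + PR_i · t,        t in days
  BASE_i, SR_i, PR_i ~ lognormal(θ, ω),  log TS_obs ~ Normal(log TS_i(t), σ)
  ```

  is fitted by MCMC; posterior-mean individual parameters give each patient
  a model-interpolated *percentage tumour reduction* PTR(w) = (BASE −
  TS(7w))/BASE at weeks 2–10.  These shrinkage metrics plus baseline
  covariates enter a Bayesian accelerated-failure-time (AFT) survival
  model — lognormal `log T ~ Normal(µ, σ)` or Weibull `S(t) =
  exp(−(t/λ)^α)` — with censored likelihood, PSIS-LOO model comparison,
  forward covariate selection, and posterior population survival curves.
  The acceleration factor exp(θ_x·Δ) is the multiplicative change in median
  survival per Δ-unit covariate increase.

* **Empirical route (COX).** Baseline variables are screened by
  LASSO-penalised Cox regression (k-fold cross-validated partial-likelihood
  deviance, at most 10 selected variables, multiple imputation below a 30 %
  missingness cap), then reduced by backward deletion at α = 0.05 in a Cox
  proportional-hazards model with Breslow ties, Schoenfeld/time-interaction
  PH diagnostics, 1000-resample bootstrap CIs and optimism-corrected
  Harrell concordance.  The observed best shrinkage within 12 weeks
  (PTR_max) is the empirical counterpart of the model-derived PTR.

Both routes are validated on a held-out cohort with time-dependent AUROC at
3/6/9/12 months and an integrated AUROC weighted by 2·f̂(t)·Ŝ(t) from the
Kaplan–Meier estimate.

Because the underlying trial data are not public, the package ships a
synthetic-cohort generator (`tgisurv.synthetic`) that reproduces the
statistical structure of a gemcitabine control arm — lognormal individual
kinetics, the 8-week scan schedule with lognormal measurement noise,
realistic covariate distributions, AFT-linked death times and
administrative censoring — with the generating truth retained so every
stage is testable by parameter recovery.

## Worked example

```bash
tgisurv synth --n 120 --seed 42 --out train/
tgisurv synth --n 235 --seed 43 --out valid/
tgisurv run-par --train train/ --validate valid/ --seed 1 --out par.json
tgisurv report par.json
```

Library use, with the numbers it prints:

```python
>>> import numpy as np
>>> from tgisurv import AFTParams, IndividualKinetics, compute_ptr
>>> from tgisurv.aft import acceleration_factor, median_survival
>>> typical = IndividualKinetics(base=np.exp(4.58), sr=np.exp(-6.78), pr=np.exp(-3.17))
>>> round(100 * compute_ptr(typical, 10), 2)   # % shrinkage at week 10
4.63
>>> ln = AFTParams(dist="lognormal", theta0=1.25,
...                coeffs={"TS0": -0.001, "PTR_wk2": 1.07, "ALB": 0.0079},
...                sigma_ln=0.544)
>>> round(acceleration_factor(ln, "PTR_wk2", 1.0), 2)  # AF per unit shrinkage fraction
2.92
>>> round(acceleration_factor(ln, "TS0", 10.0), 3)     # AF per cm of baseline tumour
0.99
```

The typical patient (97.5 mm baseline, shrinkage rate 1.14·10⁻³/day,
regrowth 4.2·10⁻² mm/day) loses 4.63 % of tumour burden by week 10; a
patient whose tumour shrinks a full baseline-fraction faster by week 2 has
a 2.92-fold longer median survival, while each extra centimetre of baseline
tumour shortens it by about 1 %.  The intercept θ₀ = 1.25 corresponds to a
typical median survival of `exp(exp(1.25)) ≈ 32.8` weeks.

## Layout

| module | contents |
| --- | --- |
| `tgisurv.synthetic` | cohort generator with retained truth |
| `tgisurv.kinetics` | tumour-size model, hierarchical MCMC, PTR metrics |
| `tgisurv.screening` | imputation, standardisation, LASSO-Cox selection |
| `tgisurv.aft` | Bayesian AFT models, LOO, forward selection, curves |
| `tgisurv.cox` | Cox PH fitting, diagnostics, bootstrap, concordance |
| `tgisurv.validation` | Kaplan–Meier, time-dependent and integrated AUROC |
| `tgisurv.pipeline` / `tgisurv.cli` | end-to-end workflows and CLI verbs |

See `docs/methods.md` for model details, priors, numerical choices and
limitations.
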