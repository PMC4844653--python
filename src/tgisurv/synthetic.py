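"""Synthetic metastatic-pancreatic-cancer cohorts for testing the pipeline.

The generator reproduces the statistical structure the analysis assumes:
lognormally distributed individual tumour kinetics around population values,
an 8-week RECIST scan schedule with multiplicative lognormal measurement
noise, baseline covariates with realistic medians/ranges, death times from
an accelerated-failure-time model linked to baseline tumour size, early
tumour shrinkage and albumin, and administrative censoring at the end of
follow-up.  Per-patient generating truth is kept for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AFTParams, CohortConfig, ConfigurationError, WEEK_DAYS

__all__ = [
    "SyntheticCohort",
    "generate_covariates",
    "draw_kinetics",
    "simulate_ts_series",
    "simulate_survival",
    "generate_cohort",
]


@dataclass
class SyntheticCohort:
    """One simulated cohort plus its generating truth."""

    covariates: pd.DataFrame
    ts_series: pd.DataFrame
    survival: pd.DataFrame
    truth: dict


def generate_covariates(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one row of baseline covariates per patient.

    Continuous variables come from the configured normal/lognormal
    distributions clipped to their physiologic ranges; categoricals are
    Bernoulli draws.  Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_patients
    cols: dict[str, np.ndarray] = {}
    for spec in config.covariate_specs:
        if spec.kind == "normal":
            x = rng.normal(spec.location, spec.spread, size=n)
        elif spec.kind == "lognormal":
            x = np.exp(rng.normal(spec.location, spec.spread, size=n))
        elif spec.kind == "bernoulli":
            x = (rng.uniform(size=n) < spec.location).astype(float)
        else:  # pragma: no cover - guarded by CovariateSpec
            raise ConfigurationError(f"unknown covariate kind {spec.kind!r}")
        if spec.kind != "bernoulli":
            lo = -np.inf if spec.lower is None else spec.lower
            hi = np.inf if spec.upper is None else spec.upper
            x = np.clip(x, lo, hi)
        cols[spec.name] = x
    out = pd.DataFrame(cols, index=pd.RangeIndex(n, name="patient_id"))
    return out


def draw_kinetics(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Lognormal individual kinetic parameters (BASE mm, SR 1/day, PR mm/day)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pop = config.ts_pop_params
    n = config.n_patients
    data = {
        "BASE": np.exp(rng.normal(pop.theta_base, pop.omega_base, size=n)),
        "SR": np.exp(rng.normal(pop.theta_sr, pop.omega_sr, size=n)),
        "PR": np.exp(rng.normal(pop.theta_pr, pop.omega_pr, size=n)),
    }
    return pd.DataFrame(data, index=pd.RangeIndex(n, name="patient_id"))


def _predict_matrix(kin: pd.DataFrame, t_days: np.ndarray) -> np.ndarray:
    base = kin["BASE"].to_numpy()[:, None]
    sr = kin["SR"].to_numpy()[:, None]
    pr = kin["PR"].to_numpy()[:, None]
    return base * np.exp(-sr * t_days[None, :]) + pr * t_days[None, :]


def simulate_ts_series(
    kinetics: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    followup_weeks: np.ndarray | None = None,
    baseline_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scheduled scans with multiplicative lognormal measurement noise.

    Scans occur at week 0 and every ``assessment_interval`` up to
    ``max_followup``, truncated at each patient's follow-up time (death or
    censoring) when ``followup_weeks`` is given.  ``baseline_values`` lets
    the caller pin the observed week-0 scan (so the TS0 covariate and the
    series agree).  With probability ``p_no_scans`` a patient keeps only the
    baseline scan, exercising the downstream evaluability filter.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if (kinetics["BASE"] <= 0).any() or (kinetics[["SR", "PR"]] < 0).any().any():
        raise ConfigurationError("kinetic parameters must be positive (rates may be zero)")
    n = len(kinetics)
    sched = np.arange(0.0, config.max_followup + 1e-9, config.assessment_interval)
    pred = _predict_matrix(kinetics, sched * WEEK_DAYS)
    noise = np.exp(config.ts_pop_params.sigma_ts * rng.standard_normal(pred.shape))
    obs = pred * noise
    if baseline_values is not None:
        obs[:, 0] = baseline_values
    fup = np.full(n, config.max_followup) if followup_weeks is None else np.asarray(followup_weeks, float)
    drop = rng.uniform(size=n) < config.p_no_scans
    rows = []
    ids = kinetics.index.to_numpy()
    for i in range(n):
        keep = sched <= fup[i] + 1e-9
        if drop[i]:
            keep = sched == 0.0
        for t, y in zip(sched[keep], obs[i, keep]):
            rows.append((ids[i], t, y))
    return pd.DataFrame(rows, columns=["patient_id", "time_weeks", "ts_mm"])


def simulate_survival(
    covariates: pd.DataFrame,
    ptr_truth: pd.Series,
    aft_truth: AFTParams,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Death times from the configured AFT truth + administrative censoring.

    ``ptr_truth`` supplies each patient's true early-shrinkage fraction for
    the ``PTR_*`` coefficient of the truth model.  Covariates named in the
    truth's ``centers`` are centered there; otherwise continuous non-PTR
    covariates are centered at the cohort median (mirroring how the survival
    models are parameterised).  Returns the observed records (time in weeks,
    event indicator) and the uncensored true death times.
    """
    from .aft import location_parameter

    rng = np.random.default_rng(config.seed) if rng is None else rng
    frame = covariates.copy()
    for name in aft_truth.coeffs:
        if name.startswith("PTR"):
            frame[name] = ptr_truth.reindex(frame.index).to_numpy()
    centers = dict(aft_truth.centers)
    for name in aft_truth.coeffs:
        if name not in centers:
            centers[name] = 0.0 if name.startswith("PTR") else float(frame[name].median())
    params = aft_truth.with_centers(centers)
    n = len(frame)
    loc = location_parameter(params, frame)
    if params.dist == "lognormal":
        death = np.exp(loc + params.sigma_ln * rng.standard_normal(n))
    else:
        death = loc * (-np.log(rng.uniform(size=n))) ** (1.0 / params.alpha)
    censor = np.full(n, config.max_followup)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    surv = pd.DataFrame(
        {"time_weeks": time, "event": event},
        index=pd.Index(frame.index, name="patient_id"),
    )
    return surv, death


def _true_ptr(kin: pd.DataFrame, week: float) -> pd.Series:
    t = week * WEEK_DAYS
    frac = 1.0 - np.exp(-kin["SR"] * t) - kin["PR"] * t / kin["BASE"]
    return frac


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a full cohort: covariates, scans, survival, generating truth."""
    rng = np.random.default_rng(config.seed)
    kin = draw_kinetics(config, rng)
    covariates = generate_covariates(config, rng)
    # observed baseline scan defines the TS0 covariate
    y0 = kin["BASE"].to_numpy() * np.exp(config.ts_pop_params.sigma_ts * rng.standard_normal(len(kin)))
    if "TS0" in covariates.columns:
        covariates["TS0"] = y0
    ptr2 = _true_ptr(kin, 2.0)
    surv, death = simulate_survival(covariates, ptr2, config.aft_truth, config, rng)
    ts = simulate_ts_series(
        kin, config, rng, followup_weeks=surv["time_weeks"].to_numpy(), baseline_values=y0
    )
    # missing-completely-at-random masks for screening tests
    for name, rate in config.missing_rates.items():
        if name in covariates.columns and rate > 0:
            mask = rng.uniform(size=len(covariates)) < rate
            covariates.loc[mask, name] = np.nan
    truth = {
        "kinetics": kin,
        "death_times_weeks": pd.Series(death, index=kin.index, name="death_weeks"),
        "ptr_wk2_true": ptr2.rename("PTR_wk2_true"),
        "pop_params": config.ts_pop_params,
        "aft_params": config.aft_truth,
    }
    return SyntheticCohort(covariates=covariates, ts_series=ts, survival=surv, truth=truth)
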