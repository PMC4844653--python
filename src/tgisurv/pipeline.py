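"""End-to-end orchestration of the parametric (PAR) and Cox (COX) workflows.

The PAR route: evaluability filter -> hierarchical tumour-size fit -> PTR
metrics -> lognormal/Weibull AFT fits -> LOO comparison -> acceleration
factors -> population survival curve -> time-dependent AUROC on a held-out
cohort.  The COX route: LASSO screening -> backward deletion -> PH checks ->
bootstrap CIs -> optimism-corrected concordance -> time-dependent AUROC.
Both emit JSON-serialisable reports carrying every fitted number and
diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aft as aft_mod
from . import cox as cox_mod
from . import kinetics as kin_mod
from . import screening as scr_mod
from . import validation as val_mod
from .config import DEFAULT_HORIZONS_WEEKS, SamplerConfig

__all__ = ["RunConfig", "PipelineData", "run_par_pipeline", "run_cox_pipeline"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: covariate presets mirroring the published models
AFT_LN_COVARIATES = ("TS0", "PTR_wk2", "ALB")
AFT_WB_COVARIATES = ("TS0", "BSA")
COX1_COVARIATES = ("TS0", "PTR_max")
COX2_COVARIATES = ("NEUT",)

#: reporting increments for acceleration factors / hazard ratios
REPORT_DELTAS = {"TS0": 10.0, "ALB": 10.0, "PTR_wk2": 1.0, "PTR_max": 1.0, "BSA": 1.0, "NEUT": 1.0}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineData:
    """Input frames for one cohort."""

    covariates: pd.DataFrame
    ts_series: pd.DataFrame
    survival: pd.DataFrame

    @classmethod
    def from_cohort(cls, cohort) -> "PipelineData":
        return cls(cohort.covariates, cohort.ts_series, cohort.survival)

    @classmethod
    def from_dir(cls, directory) -> "PipelineData":
        from .io import read_cohort_dir

        return cls(*read_cohort_dir(directory))

    def validate(self, stage: str) -> None:
        if len(self.covariates) == 0 or len(self.survival) == 0:
            raise PipelineError(f"{stage}: empty cohort")
        if (self.survival["time_weeks"] <= 0).any():
            raise PipelineError(f"{stage}: non-positive survival times")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    ts_sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(warmup=1500, iters=500, thin=12))
    aft_sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(warmup=1500, iters=500, thin=5))
    horizons: tuple[float, ...] = DEFAULT_HORIZONS_WEEKS
    bootstrap_B: int = 200
    concordance_B: int = 50
    n_curve_draws: int = 1000
    forward_selection: bool = False
    screen_max_vars: int = 10
    screen_folds: int = 10


def _ptr_frame(data: PipelineData, sampler: SamplerConfig) -> tuple[pd.DataFrame, dict]:
    """Hierarchical fit + PTR metric table for one cohort."""
    posterior = kin_mod.fit_hierarchical(data.ts_series, sampler)
    report = kin_mod.check_convergence(posterior)
    ptr = kin_mod.ptr_metrics_table(posterior.individual_means, data.ts_series)
    diag = {
        "n_evaluable": len(posterior.patient_ids),
        "rhat_max": report.max_rhat,
        "converged": report.passed,
        "posterior_summary": posterior.summary(),
    }
    return ptr, diag


def _assemble(data: PipelineData, ptr: pd.DataFrame, needed: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join covariates + PTR metrics, keep complete cases for `needed`."""
    frame = data.covariates.join(ptr, how="inner")
    frame = frame.dropna(subset=[c for c in needed if c in frame.columns])
    records = data.survival.loc[frame.index]
    return frame, records


def run_par_pipeline(
    train: PipelineData,
    validate: PipelineData | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Parametric tumour-kinetics + AFT survival workflow."""
    config = config or RunConfig()
    train.validate("par/train")
    ptr_train, kin_diag = _ptr_frame(train, config.ts_sampler)
    needed = sorted(set(AFT_LN_COVARIATES) | set(AFT_WB_COVARIATES))
    frame, records = _assemble(train, ptr_train, needed)
    if records["event"].sum() < 5:
        raise PipelineError("par: too few events in the reduced-training set")

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "kinetics": kin_diag,
        "n_reduced_training": len(frame),
        "n_events": int(records["event"].sum()),
        "km_median_weeks": val_mod.kaplan_meier(records).median,
        "models": {},
    }

    sampler = SamplerConfig(
        chains=config.aft_sampler.chains, warmup=config.aft_sampler.warmup,
        iters=config.aft_sampler.iters, thin=config.aft_sampler.thin, seed=config.seed,
    )
    fits: dict[str, aft_mod.AFTFit] = {}
    for name, dist, preset in (
        ("AFT_LN", "lognormal", AFT_LN_COVARIATES),
        ("AFT_WB", "weibull", AFT_WB_COVARIATES),
    ):
        if config.forward_selection:
            selected, path_fits = aft_mod.forward_select(records, frame, dist, list(preset), sampler)
            fit = path_fits["+".join(selected)] if selected else path_fits[""]
            covs = selected
        else:
            covs = [c for c in preset if c in frame.columns]
            fit = aft_mod.fit_aft(records, frame, dist, covs, sampler)
        elpd, se, k = aft_mod.psis_loo(fit)
        params = fit.posterior_mean_params
        af = {
            v: {
                "delta": REPORT_DELTAS.get(v, 1.0),
                "af": aft_mod.acceleration_factor(params, v, REPORT_DELTAS.get(v, 1.0)),
                "ci95_coef": fit.credible_interval(f"theta_{v}"),
            }
            for v in covs
        }
        curve = aft_mod.simulate_population_curve(
            fit, frame, n_draws=config.n_curve_draws, seed=config.seed
        )
        fits[name] = fit
        report["models"][name] = {
            "dist": dist,
            "covariates": list(covs),
            "posterior_summary": fit.summary(),
            "rhat_max": float(np.nanmax(list(fit.rhat.values()))),
            "elpd_loo": elpd,
            "elpd_loo_se": se,
            "pareto_k_max": float(np.max(k)),
            "acceleration_factors": af,
            "typical_median_weeks": float(
                np.median(aft_mod.median_survival(params, frame))
            ),
            "population_curve": curve,
        }

    if validate is not None:
        validate.validate("par/validate")
        ptr_val, kin_diag_val = _ptr_frame(validate, config.ts_sampler)
        report["kinetics_validation"] = kin_diag_val
        horizons = np.asarray(config.horizons, dtype=float)
        preds: dict[str, pd.DataFrame] = {}
        frames_val: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
        for name, fit in fits.items():
            fv, rv = _assemble(validate, ptr_val, fit.covariate_names)
            params = fit.posterior_mean_params
            s = aft_mod.survivor_function(params, fv, horizons)
            preds[name] = pd.DataFrame(s, index=fv.index, columns=horizons)
            frames_val[name] = (fv, rv)
        # all models share the evaluable validation patients: align on intersection
        common = None
        for fv, _ in frames_val.values():
            common = fv.index if common is None else common.intersection(fv.index)
        records_val = validate.survival.loc[common]
        preds = {k: v.loc[common] for k, v in preds.items()}
        report["validation_auroc"] = val_mod.evaluate_at_horizons(
            preds, records_val, horizons=tuple(horizons), seed=config.seed
        )
        # integrated AUROC over the event-time grid
        integrated = {}
        ev_times = np.unique(
            records_val.loc[records_val["event"] == 1, "time_weeks"].to_numpy()
        )
        grid = [t for t in ev_times if 0 < t < records_val["time_weeks"].max()]
        for name, fit in fits.items():
            params = fit.posterior_mean_params
            fv = frames_val[name][0].loc[common]
            s_grid = aft_mod.survivor_function(params, fv, np.asarray(grid))
            vals = {}
            for j, t in enumerate(grid):
                try:
                    res = val_mod.time_dependent_auroc(-s_grid[:, j], records_val, t, n_boot=0)
                    vals[t] = res.auroc
                except val_mod.ValidationError:
                    continue
            if len(vals) >= 2:
                integrated[name] = val_mod.integrated_auroc(pd.Series(vals), records_val)
        report["integrated_auroc"] = integrated
    return report


def run_cox_pipeline(
    train: PipelineData,
    validate: PipelineData | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Empirical risk-factor workflow with Cox regression."""
    config = config or RunConfig()
    train.validate("cox/train")
    # PTR_max from observed scans
    ptr_max = {}
    for pid in kin_mod.filter_evaluable(train.ts_series):
        series = train.ts_series[train.ts_series["patient_id"] == pid]
        ptr_max[pid] = kin_mod.compute_ptr_max(series)
    ptr = pd.DataFrame({"PTR_max": pd.Series(ptr_max)})
    ptr.index.name = "patient_id"

    screen_res = scr_mod.screen_covariates(
        train.covariates, train.survival,
        k_folds=config.screen_folds, max_vars=config.screen_max_vars, seed=config.seed,
    )

    frame, records = _assemble(train, ptr, ["PTR_max", "TS0", "NEUT"])
    frame = scr_mod.log_transform(frame, ("NEUT",))  # COX_2 uses log neutrophils
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "screening": {
            "selected": screen_res["selected"],
            "dropped": screen_res["dropped"],
            "votes": screen_res["votes"],
        },
        "n_reduced_training": len(frame),
        "n_events": int(records["event"].sum()),
        "km_median_weeks": val_mod.kaplan_meier(records).median,
        "models": {},
    }

    fits: dict[str, cox_mod.CoxFit] = {}
    for name, preset in (("COX_1", COX1_COVARIATES), ("COX_2", COX2_COVARIATES)):
        X = frame[list(preset)]
        fit = cox_mod.backward_eliminate(X, records, alpha=0.05)
        if not fit.variables:  # presets are reported even if deletion empties them
            fit = cox_mod.fit_cox(X, records)
        ci = cox_mod.bootstrap_ci(X[fit.variables], records, B=max(config.bootstrap_B, 100), seed=config.seed)
        conc = cox_mod.optimism_corrected_concordance(
            X[fit.variables], records, B=max(config.concordance_B, 50), seed=config.seed
        )
        ph = cox_mod.ph_diagnostics(fit, frame, records)
        hr = {
            v: {
                "delta": REPORT_DELTAS.get(v, 1.0),
                "hr": cox_mod.hazard_ratio(fit, v, REPORT_DELTAS.get(v, 1.0)),
                "ci95_coef": (float(ci.loc[v, "lo"]), float(ci.loc[v, "hi"])),
            }
            for v in fit.variables
        }
        fits[name] = fit
        report["models"][name] = {
            "variables": fit.variables,
            "coefficients": fit.coefficients,
            "p_values": fit.p_values,
            "hazard_ratios": hr,
            "ph_diagnostics": ph,
            "concordance": conc,
        }

    if validate is not None:
        validate.validate("cox/validate")
        ptr_max_val = {}
        for pid in kin_mod.filter_evaluable(validate.ts_series):
            series = validate.ts_series[validate.ts_series["patient_id"] == pid]
            ptr_max_val[pid] = kin_mod.compute_ptr_max(series)
        ptr_val = pd.DataFrame({"PTR_max": pd.Series(ptr_max_val)})
        ptr_val.index.name = "patient_id"
        frame_val, records_val = _assemble(validate, ptr_val, ["PTR_max", "TS0", "NEUT"])
        frame_val = scr_mod.log_transform(frame_val, ("NEUT",))
        horizons = np.asarray(config.horizons, dtype=float)
        preds = {}
        for name, fit in fits.items():
            S = cox_mod.predict_survival_probability(fit, frame_val, horizons)
            preds[name] = pd.DataFrame(S, index=frame_val.index, columns=horizons)
        report["validation_auroc"] = val_mod.evaluate_at_horizons(
            preds, records_val, horizons=tuple(horizons), seed=config.seed
        )
        integrated = {}
        ev_times = np.unique(records_val.loc[records_val["event"] == 1, "time_weeks"].to_numpy())
        grid = [t for t in ev_times if 0 < t < records_val["time_weeks"].max()]
        for name, fit in fits.items():
            s_grid = cox_mod.predict_survival_probability(fit, frame_val, np.asarray(grid))
            vals = {}
            for j, t in enumerate(grid):
                try:
                    res = val_mod.time_dependent_auroc(-s_grid[:, j], records_val, t, n_boot=0)
                    vals[t] = res.auroc
                except val_mod.ValidationError:
                    continue
            if len(vals) >= 2:
                integrated[name] = val_mod.integrated_auroc(pd.Series(vals), records_val)
        report["integrated_auroc"] = integrated
    return report
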