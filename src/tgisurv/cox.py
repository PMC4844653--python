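"""Multivariate Cox proportional-hazards modelling (the empirical route).

Coefficient estimation goes through lifelines (Breslow tie handling); the
Breslow baseline cumulative hazard, survival prediction, backward deletion,
proportional-hazards diagnostics, bootstrap confidence intervals and the
optimism-corrected concordance are computed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.statistics import proportional_hazard_test
from lifelines.utils import concordance_index

__all__ = [
    "CoxFit",
    "fit_cox",
    "hazard_ratio",
    "backward_eliminate",
    "ph_diagnostics",
    "bootstrap_ci",
    "optimism_corrected_concordance",
    "predict_survival_probability",
]

logger = logging.getLogger(__name__)


class CoxError(ValueError):
    pass


@dataclass
class CoxFit:
    """Fitted proportional-hazards model.

    ``baseline_hazard`` is the Breslow cumulative hazard evaluated at the
    centering point (covariates equal to ``centers``); risk scores are
    exp((x - centers) . beta).
    """

    variables: list[str]
    coefficients: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    baseline_hazard: pd.DataFrame  # columns: time_weeks, cum_hazard
    centers: pd.Series
    p_values: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    standard_errors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def risk_score(self, covariates: pd.DataFrame) -> np.ndarray:
        """Linear predictor (x - centers) . beta; zero for the empty model."""
        if not self.variables:
            return np.zeros(len(covariates))
        Xc = covariates[self.variables].to_numpy(dtype=float) - self.centers.to_numpy()
        return Xc @ self.coefficients.to_numpy()


def _check_inputs(X: pd.DataFrame, records: pd.DataFrame) -> None:
    if records["event"].sum() < 1:
        raise CoxError("need at least one event")
    for col in X.columns:
        if np.isclose(X[col].std(ddof=0), 0.0):
            raise CoxError(f"constant column {col!r}")


def _breslow_baseline(
    time: np.ndarray, event: np.ndarray, risk: np.ndarray
) -> pd.DataFrame:
    """Breslow cumulative hazard H0(t) at the centering point."""
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    r_sorted = np.exp(risk[order])
    # risk-set sums via reverse cumulative sum; ties share the same risk set
    rev_cum = np.cumsum(r_sorted[::-1])[::-1]
    uniq_times = np.unique(t_sorted[e_sorted.astype(bool)])
    h0 = []
    cum = 0.0
    for t in uniq_times:
        d = np.sum((t_sorted == t) & e_sorted.astype(bool))
        at_risk = rev_cum[np.searchsorted(t_sorted, t, side="left")]
        cum += d / at_risk
        h0.append((t, cum))
    return pd.DataFrame(h0, columns=["time_weeks", "cum_hazard"])


def fit_cox(X: pd.DataFrame, records: pd.DataFrame) -> CoxFit:
    """Breslow partial-likelihood fit; covariates centered at their mean.

    An empty covariate table yields the null model whose baseline hazard is
    the Nelson-Aalen estimate.
    """
    records = records.loc[X.index] if len(X) else records
    time = records["time_weeks"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=float)
    if event.sum() < 1:
        raise CoxError("need at least one event")
    if X.shape[1] == 0:
        baseline = _breslow_baseline(time, event, np.zeros(len(records)))
        return CoxFit(
            variables=[],
            coefficients=pd.Series(dtype=float),
            covariance=pd.DataFrame(),
            log_likelihood=float("nan"),
            baseline_hazard=baseline,
            centers=pd.Series(dtype=float),
        )
    _check_inputs(X, records)
    df = X.copy()
    df["time_weeks"] = time
    df["event"] = event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_weeks", event_col="event")
    beta = cph.params_.copy()
    centers = X.mean()
    risk = (X.to_numpy(dtype=float) - centers.to_numpy()) @ beta.to_numpy()
    baseline = _breslow_baseline(time, event, risk)
    return CoxFit(
        variables=list(X.columns),
        coefficients=beta,
        covariance=cph.variance_matrix_,
        log_likelihood=float(cph.log_likelihood_),
        baseline_hazard=baseline,
        centers=centers,
        p_values=cph.summary["p"].copy(),
        standard_errors=cph.summary["se(coef)"].copy(),
    )


def hazard_ratio(fit: CoxFit, variable: str, delta: float = 1.0) -> float:
    """exp(beta * delta): hazard ratio per delta-unit covariate increase."""
    if variable not in fit.coefficients.index:
        raise CoxError(f"unknown variable {variable!r}")
    return float(np.exp(fit.coefficients[variable] * delta))


def backward_eliminate(X: pd.DataFrame, records: pd.DataFrame, alpha: float = 0.05) -> CoxFit:
    """Drop the least significant variable (Wald p >= alpha) until all pass."""
    cols = list(X.columns)
    if not cols:
        raise CoxError("need at least one candidate variable")
    while cols:
        fit = fit_cox(X[cols], records)
        worst = fit.p_values.idxmax()
        if fit.p_values[worst] >= alpha:
            cols.remove(worst)
        else:
            return fit
    return fit_cox(X[[]], records)


def _episode_split(X: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Counting-process layout cut at the unique event times."""
    time = records["time_weeks"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    cuts = np.unique(time[event])
    rows = []
    for pid, t_i, e_i, x_i in zip(records.index, time, event, X.to_numpy(dtype=float)):
        inner = cuts[cuts < t_i]
        starts = np.concatenate([[0.0], inner])
        stops = np.concatenate([inner, [t_i]])
        for s, st in zip(starts, stops):
            rows.append((pid, s, st, bool(e_i) and st == t_i, *x_i))
    return pd.DataFrame(rows, columns=["id", "start", "stop", "event", *X.columns])


def ph_diagnostics(fit: CoxFit, X: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Proportional-hazards checks for every model variable.

    Two complementary tests per variable: a Wald test of a linear
    variable-by-time interaction in a time-varying Cox refit, and the
    scaled-Schoenfeld zero-slope score test on untransformed time.  Small
    p-values indicate a time-varying effect, i.e. a PH violation.
    """
    if not fit.variables:
        raise CoxError("PH diagnostics need a fitted model with >=1 variable")
    X = X[fit.variables]
    # (a) time-interaction refits
    p_inter = {}
    episodes = _episode_split(X, records)
    for var in fit.variables:
        df = episodes[["id", "start", "stop", "event", *fit.variables]].copy()
        df[f"{var}_x_t"] = df[var] * df["stop"]
        ctv = CoxTimeVaryingFitter()
        ctv.fit(df, id_col="id", start_col="start", stop_col="stop", event_col="event")
        p_inter[var] = float(ctv.summary.loc[f"{var}_x_t", "p"])
    # (b) scaled Schoenfeld residual zero-slope test (identity time transform)
    df = X.copy()
    df["time_weeks"] = records["time_weeks"].to_numpy(dtype=float)
    df["event"] = records["event"].to_numpy(dtype=float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_weeks", event_col="event")
    res = proportional_hazard_test(cph, df, time_transform="identity")
    schoen = res.summary["p"]
    if isinstance(schoen.index, pd.MultiIndex):
        schoen = schoen.droplevel(-1)
    return pd.DataFrame(
        {
            "p_time_interaction": pd.Series(p_inter),
            "p_schoenfeld": schoen.reindex(fit.variables),
        }
    )


def bootstrap_ci(
    X: pd.DataFrame,
    records: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Patient-level bootstrap percentile CIs for the Cox coefficients."""
    if B < 100:
        raise CoxError("need at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n = len(records)
    boots = np.empty((B, X.shape[1]))
    redraws = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        rec_b = records.iloc[idx].reset_index(drop=True)
        X_b = X.iloc[idx].reset_index(drop=True)
        if rec_b["event"].sum() < 1 or any(np.isclose(X_b[c].std(ddof=0), 0) for c in X_b):
            redraws += 1
            continue
        try:
            fit_b = fit_cox(X_b, rec_b)
        except Exception:
            redraws += 1
            continue
        boots[b] = fit_b.coefficients.to_numpy()
        b += 1
    if redraws:
        logger.info("bootstrap_ci: redrew %d degenerate resamples", redraws)
    a = (1.0 - level) / 2.0
    return pd.DataFrame(
        {
            "lo": np.quantile(boots, a, axis=0),
            "hi": np.quantile(boots, 1.0 - a, axis=0),
        },
        index=X.columns,
    )


def _harrell_c(time: np.ndarray, risk: np.ndarray, event: np.ndarray) -> float:
    try:
        return float(concordance_index(time, -risk, event))
    except ZeroDivisionError as err:
        raise CoxError("no comparable pairs for the concordance index") from err


def optimism_corrected_concordance(
    X: pd.DataFrame, records: pd.DataFrame, B: int = 200, seed: int = 0
) -> dict[str, float]:
    """Harrell's c corrected for optimism by the bootstrap.

    optimism = mean over resamples of (c of the bootstrap fit on its own
    sample - c of that fit on the original data); corrected c = apparent c -
    optimism.
    """
    if B < 50:
        raise CoxError("need at least 50 bootstrap resamples")
    fit = fit_cox(X, records)
    time = records["time_weeks"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=float)
    apparent = _harrell_c(time, fit.risk_score(X), event)
    rng = np.random.default_rng(seed)
    n = len(records)
    optimism = []
    while len(optimism) < B:
        idx = rng.integers(0, n, size=n)
        rec_b = records.iloc[idx].reset_index(drop=True)
        X_b = X.iloc[idx].reset_index(drop=True)
        if rec_b["event"].sum() < 1 or any(np.isclose(X_b[c].std(ddof=0), 0) for c in X_b):
            continue
        try:
            fit_b = fit_cox(X_b, rec_b)
        except Exception:
            continue
        c_boot = _harrell_c(
            rec_b["time_weeks"].to_numpy(float), fit_b.risk_score(X_b), rec_b["event"].to_numpy(float)
        )
        c_orig = _harrell_c(time, fit_b.risk_score(X), event)
        optimism.append(c_boot - c_orig)
    corrected = apparent - float(np.mean(optimism))
    return {"apparent": apparent, "optimism": float(np.mean(optimism)), "corrected": corrected}


def predict_survival_probability(
    fit: CoxFit, covariates: pd.DataFrame, t
) -> np.ndarray:
    """S(t | x) = exp(-H0(t))^exp(risk); step function in t.

    ``t`` may be a scalar (returns one value per patient) or an array
    (returns (n_patients, n_times)).  Beyond the last event time the last
    value is carried forward with a warning.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise CoxError("time must be non-negative")
    bh = fit.baseline_hazard
    grid = bh["time_weeks"].to_numpy()
    h0 = bh["cum_hazard"].to_numpy()
    if np.any(t_arr > grid[-1]):
        warnings.warn(
            "prediction beyond the last event time: carrying the last survival value forward",
            stacklevel=2,
        )
    pos = np.searchsorted(grid, t_arr, side="right") - 1
    H = np.where(pos >= 0, h0[np.clip(pos, 0, len(h0) - 1)], 0.0)
    risk = np.exp(fit.risk_score(covariates))
    S = np.exp(-np.outer(risk, H))
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return S[:, 0]
    return S
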