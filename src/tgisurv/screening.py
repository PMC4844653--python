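"""Baseline-variable screening with LASSO-penalised Cox regression.

Workflow: impute missing values (variables with >= 30 % missing are
dropped), log-transform the heavily skewed markers, standardise continuous
variables, then trace the L1 penalty path of a Cox model and pick the
penalty by k-fold cross-validated partial-likelihood deviance subject to an
upper bound on the number of selected variables.  With multiply imputed
tables, variables selected in a majority of completed tables are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "LassoPath",
    "impute_missing",
    "standardize",
    "destandardize",
    "log_transform",
    "fit_lasso_cox",
    "lasso_path",
    "select_variables",
    "screen_covariates",
]

logger = logging.getLogger(__name__)

MISSING_LIMIT = 0.30  # variables at or above this missing fraction are dropped
DEFAULT_LOG_COLUMNS = ("ALP", "CA19_9", "NEUT")


class ScreeningError(ValueError):
    pass


def _is_binary(col: pd.Series) -> bool:
    vals = set(col.dropna().unique())
    return vals <= {0, 1, 0.0, 1.0}


def log_transform(table: pd.DataFrame, columns=DEFAULT_LOG_COLUMNS) -> pd.DataFrame:
    """Natural log of the named (strictly positive, skewed) columns."""
    out = table.copy()
    for c in columns:
        if c in out.columns:
            if (out[c].dropna() <= 0).any():
                raise ScreeningError(f"cannot log-transform non-positive values in {c!r}")
            out[c] = np.log(out[c])
    return out


def impute_missing(
    table: pd.DataFrame,
    event: pd.Series,
    m: int = 5,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list[str]]:
    """Stochastic regression imputation conditional on complete columns + outcome.

    Each incomplete variable is regressed (least squares) on the fully
    observed variables and the event indicator using its complete cases;
    missing entries are filled with the prediction plus resampled Gaussian
    noise (binary variables: Bernoulli draws from the clipped prediction).
    Variables with >= 30 % missingness are dropped with a warning.  Returns
    ``m`` completed tables and the list of dropped variables.
    """
    frac = table.isna().mean()
    dropped = [c for c in table.columns if frac[c] >= MISSING_LIMIT]
    for c in dropped:
        logger.warning("dropping %s: %.0f %% missing (>= %d %% rule)", c, 100 * frac[c], 100 * MISSING_LIMIT)
    kept = table.drop(columns=dropped)
    complete_cols = [c for c in kept.columns if kept[c].notna().all()]
    incomplete = [c for c in kept.columns if c not in complete_cols]
    ev = event.reindex(kept.index).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(m):
        out = kept.copy()
        for c in incomplete:
            obs = kept[c].notna().to_numpy()
            Z = np.column_stack(
                [np.ones(len(kept))]
                + [kept[cc].to_numpy(dtype=float) for cc in complete_cols]
                + [ev]
            )
            y = kept[c].to_numpy(dtype=float)
            coef, *_ = np.linalg.lstsq(Z[obs], y[obs], rcond=None)
            pred = Z @ coef
            if _is_binary(kept[c]):
                p = np.clip(pred, 0.0, 1.0)
                fill = (rng.uniform(size=len(kept)) < p).astype(float)
            else:
                resid_sd = float(np.std(y[obs] - pred[obs], ddof=Z.shape[1]))
                fill = pred + resid_sd * rng.standard_normal(len(kept))
            out.loc[~obs, c] = fill[~obs]
        tables.append(out)
    return tables, dropped


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center/scale continuous columns to mean 0, sample SD 1.

    Binary (0/1) columns are left untouched.  Returns the standardised table
    and a constants frame (columns ``mean``, ``sd``) for back-transformation.
    """
    out = table.copy()
    consts = {}
    for c in table.columns:
        if _is_binary(table[c]):
            continue
        mu = float(table[c].mean())
        sd = float(table[c].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ScreeningError(f"zero-variance column {c!r}")
        out[c] = (table[c] - mu) / sd
        consts[c] = {"mean": mu, "sd": sd}
    return out, pd.DataFrame(consts).T


def destandardize(table: pd.DataFrame, constants: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for c in constants.index:
        out[c] = table[c] * constants.loc[c, "sd"] + constants.loc[c, "mean"]
    return out


def _breslow_pll(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray) -> float:
    """Breslow-ties Cox partial log-likelihood."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    eta = (X[order] @ beta).astype(float)
    # log of the risk-set sums by reverse accumulation
    rev_lse = np.logaddexp.accumulate(eta[::-1])[::-1]
    pll = 0.0
    for ut in np.unique(t[e]):
        at = np.searchsorted(t, ut, side="left")
        deaths = e & (t == ut)
        pll += eta[deaths].sum() - deaths.sum() * rev_lse[at]
    return float(pll)


@dataclass
class LassoPath:
    """L1 penalty path with k-fold CV partial-likelihood deviance."""

    alphas: np.ndarray
    coefs: pd.DataFrame            # (n_alphas, p)
    cv_mean: np.ndarray | None = None
    cv_se: np.ndarray | None = None

    def n_active(self) -> np.ndarray:
        return (self.coefs.to_numpy() != 0).sum(axis=1)


def _surv_y(records: pd.DataFrame):
    return Surv.from_arrays(
        event=records["event"].to_numpy(dtype=bool),
        time=records["time_weeks"].to_numpy(dtype=float),
    )


def fit_lasso_cox(X: pd.DataFrame, records: pd.DataFrame, penalty: float) -> pd.Series:
    """L1-penalised Cox coefficients at one penalty (exact zeros off-support)."""
    if records["event"].sum() < 1:
        raise ScreeningError("need at least one event")
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[max(penalty, 1e-9)], normalize=False, tol=1e-9, max_iter=500000
    )
    model.fit(X.to_numpy(dtype=float), _surv_y(records))
    return pd.Series(model.coef_[:, 0], index=X.columns)


def lasso_path(
    X: pd.DataFrame,
    records: pd.DataFrame,
    k_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
) -> LassoPath:
    """Full-data penalty path plus k-fold CV deviance per penalty."""
    n_events = int(records["event"].sum())
    if k_folds < 2:
        raise ScreeningError("k_folds must be >= 2")
    if n_events < k_folds:
        raise ScreeningError("fewer events than folds")
    Xmat = X.to_numpy(dtype=float)
    y = _surv_y(records)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01, normalize=False, max_iter=200000
    )
    model.fit(Xmat, y)
    alphas = np.asarray(model.alphas_)
    coefs = pd.DataFrame(model.coef_.T, columns=X.columns)

    time = records["time_weeks"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    folds = np.array_split(idx, k_folds)
    dev = np.full((k_folds, alphas.size), np.nan)
    for k, test in enumerate(folds):
        train = np.setdiff1d(idx, test)
        if event[test].sum() < 1 or event[train].sum() < 1:
            continue
        m_k = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(alphas), normalize=False, max_iter=200000
        )
        m_k.fit(Xmat[train], Surv.from_arrays(event=event[train].astype(bool), time=time[train]))
        fitted_alphas = np.asarray(m_k.alphas_)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted_alphas - a)))
            beta = m_k.coef_[:, jj]
            dev[k, j] = -2.0 * _breslow_pll(Xmat[test], time[test], event[test], beta)
    cv_mean = np.nanmean(dev, axis=0)
    cv_se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(dev), axis=0))
    return LassoPath(alphas=alphas, coefs=coefs, cv_mean=cv_mean, cv_se=cv_se)


def select_variables(
    X: pd.DataFrame,
    records: pd.DataFrame,
    k_folds: int = 10,
    max_vars: int = 10,
    seed: int = 0,
) -> tuple[list[str], LassoPath]:
    """CV-optimal penalty subject to <= max_vars active coefficients.

    Returns the active variable set at the chosen penalty and the path.
    """
    path = lasso_path(X, records, k_folds=k_folds, seed=seed)
    if max_vars == 0:
        return [], path
    n_active = path.n_active()
    eligible = np.flatnonzero(n_active <= max_vars)
    if eligible.size == 0:
        eligible = np.array([0])  # largest penalty: sparsest model available
    best = eligible[int(np.argmin(path.cv_mean[eligible]))]
    active = [c for c, b in zip(path.coefs.columns, path.coefs.iloc[best]) if b != 0]
    return active, path


def screen_covariates(
    table: pd.DataFrame,
    records: pd.DataFrame,
    m: int = 5,
    k_folds: int = 10,
    max_vars: int = 10,
    seed: int = 0,
    log_columns=DEFAULT_LOG_COLUMNS,
) -> dict:
    """End-to-end screening over multiply imputed tables (majority vote)."""
    tables, dropped = impute_missing(table, records["event"], m=m, seed=seed)
    votes: dict[str, int] = {}
    per_table = []
    for i, t in enumerate(tables):
        t = log_transform(t, log_columns)
        std, _ = standardize(t)
        sel, _ = select_variables(std, records, k_folds=k_folds, max_vars=max_vars, seed=seed + i)
        per_table.append(sel)
        for v in sel:
            votes[v] = votes.get(v, 0) + 1
    majority = [v for v, c in votes.items() if c > len(tables) / 2]
    return {
        "selected": sorted(majority),
        "per_table": per_table,
        "dropped": dropped,
        "votes": votes,
    }
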