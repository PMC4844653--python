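"""Censored-outcome validation: Kaplan-Meier, time-dependent and integrated AUROC.

The time-dependent AUROC at horizon t treats death by t as the positive
class and survival past t as the negative class; patients censored before t
carry an undefined status and are excluded (an inverse-probability-of-
censoring-weighted variant is available for sensitivity analysis).  The
integrated AUROC averages AUROC(t) over the observed event times with
weights proportional to 2*f(t)*S(t) estimated from the Kaplan-Meier curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "AUROCResult",
    "kaplan_meier",
    "time_dependent_auroc",
    "integrated_auroc",
    "evaluate_at_horizons",
]


class ValidationError(ValueError):
    pass


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance and log-scale 95 % CI."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # NaN when the curve never reaches 0.5

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        pos = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if pos < 0 else float(self.survival[pos])


def kaplan_meier(records: pd.DataFrame, level: float = 0.95) -> KMCurve:
    """Kaplan-Meier estimate over the distinct event times.

    The CI uses the log transform: exp(log S +/- z * sqrt(Var)/S), clipped
    to [0, 1].  The median is the first time S drops to <= 0.5.
    """
    if len(records) == 0:
        raise ValidationError("need at least one record")
    time = records["time_weeks"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e])
    n = len(t)
    surv, var_terms, times = [], [], []
    s = 1.0
    gw = 0.0
    for ut in uniq:
        at_risk = n - np.searchsorted(t, ut, side="left")
        d = int(np.sum(e & (t == ut)))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
        times.append(ut)
        surv.append(s)
        var_terms.append(gw)
    times = np.asarray(times)
    surv = np.asarray(surv)
    variance = surv**2 * np.asarray(var_terms)
    z = stats.norm.ppf(0.5 + level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_log = np.where(surv > 0, np.sqrt(np.asarray(var_terms)), np.inf)
        lo = np.clip(surv * np.exp(-z * se_log), 0.0, 1.0)
        hi = np.clip(surv * np.exp(z * se_log), 0.0, 1.0)
    lo = np.where(surv == 0, 0.0, lo)
    hi = np.where(surv == 0, 0.0, hi)
    below = np.flatnonzero(surv <= 0.5)
    median = float(times[below[0]]) if below.size else float("nan")
    return KMCurve(times=times, survival=surv, variance=variance, ci_lower=lo, ci_upper=hi, median=median)


@dataclass
class AUROCResult:
    horizon: float
    auroc: float
    ci_lower: float
    ci_upper: float
    n_cases: int
    n_controls: int


def _mann_whitney_auc(risk_cases: np.ndarray, risk_controls: np.ndarray) -> float:
    """P(case risk > control risk) with ties counting 1/2."""
    diff = risk_cases[:, None] - risk_controls[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def time_dependent_auroc(
    risk: pd.Series | np.ndarray,
    records: pd.DataFrame,
    t: float,
    n_boot: int = 1000,
    seed: int = 0,
    ipcw: bool = False,
) -> AUROCResult:
    """AUROC for death-by-t against a per-patient risk score (higher = worse).

    Cases: event time <= t with the event observed.  Controls: follow-up
    beyond t.  Censored-before-t patients are excluded (default) or, with
    ``ipcw``, cases are weighted by the inverse censoring-survival
    probability at their event time.  The CI is a patient-level bootstrap
    percentile interval.
    """
    if t <= 0:
        raise ValidationError("horizon must be positive")
    risk = np.asarray(risk, dtype=float)
    time = records["time_weeks"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    if risk.shape[0] != time.shape[0]:
        raise ValidationError("risk score length does not match records")
    cases = (time <= t) & event
    controls = time > t
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValidationError(f"no cases or no controls at horizon {t}")

    def auc_of(idx: np.ndarray) -> float:
        c = cases[idx]
        k = controls[idx]
        if c.sum() == 0 or k.sum() == 0:
            return np.nan
        if not ipcw:
            return _mann_whitney_auc(risk[idx][c], risk[idx][k])
        cens = pd.DataFrame({"time_weeks": time[idx], "event": 1 - event[idx].astype(int)})
        km_c = kaplan_meier(cens)
        w = np.array([1.0 / max(km_c.at(u - 1e-9), 1e-8) for u in time[idx][c]])
        diff = risk[idx][c][:, None] - risk[idx][k][None, :]
        wmat = w[:, None] * np.ones((1, k.sum()))
        return float(np.sum(wmat * ((diff > 0) + 0.5 * (diff == 0))) / wmat.sum())

    full = np.arange(len(time))
    auc = auc_of(full)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        b = auc_of(rng.integers(0, len(time), size=len(time)))
        if np.isfinite(b):
            boots.append(b)
    lo, hi = (np.quantile(boots, [0.025, 0.975]) if boots else (np.nan, np.nan))
    return AUROCResult(
        horizon=float(t), auroc=auc, ci_lower=float(lo), ci_upper=float(hi),
        n_cases=int(cases.sum()), n_controls=int(controls.sum()),
    )


def integrated_auroc(
    auroc_by_time: pd.Series,
    records: pd.DataFrame,
    uniform_weights: bool = False,
) -> float:
    """Weighted average of AUROC(t) over event times.

    Default weights are proportional to 2*f(t)*S(t) from the Kaplan-Meier
    estimate (the incident/dynamic convention); ``uniform_weights`` gives a
    plain mean over the grid instead.
    """
    times = np.asarray(auroc_by_time.index, dtype=float)
    vals = auroc_by_time.to_numpy(dtype=float)
    if times.size < 2:
        raise ValidationError("need AUROC on at least 2 time points")
    if uniform_weights:
        return float(vals.mean())
    km = kaplan_meier(records)
    s_prev = np.concatenate([[1.0], km.survival[:-1]])
    mass = dict(zip(km.times, s_prev - km.survival))
    s_at = dict(zip(km.times, km.survival))
    w = np.array([2.0 * mass.get(t, 0.0) * s_at.get(t, 0.0) for t in times])
    if w.sum() == 0:
        return float(vals.mean())
    w = w / w.sum()
    return float(np.sum(w * vals))


def evaluate_at_horizons(
    predictions: dict[str, pd.DataFrame],
    records: pd.DataFrame,
    horizons=(13.0, 26.0, 39.0, 52.0),
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Time-dependent AUROC per model and horizon.

    ``predictions`` maps model name -> frame of per-patient survival
    probabilities with one column per horizon (column labels = horizon in
    weeks, lower probability = higher risk).  Horizons beyond the last
    observed time are skipped with a warning.
    """
    last = records["time_weeks"].max()
    rows = []
    for name, preds in predictions.items():
        for t in horizons:
            if t > last:
                warnings.warn(f"horizon {t} beyond last observed time; skipped", stacklevel=2)
                continue
            surv_prob = preds[t] if t in preds.columns else preds[float(t)]
            res = time_dependent_auroc(
                -np.asarray(surv_prob, dtype=float), records, t, n_boot=n_boot, seed=seed
            )
            rows.append(
                {
                    "model": name,
                    "horizon_weeks": res.horizon,
                    "auroc": res.auroc,
                    "ci_lower": res.ci_lower,
                    "ci_upper": res.ci_upper,
                    "n_cases": res.n_cases,
                    "n_controls": res.n_controls,
                }
            )
    return pd.DataFrame(rows)
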