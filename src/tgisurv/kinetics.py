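"""Hierarchical modelling of tumour-size time-series and shrinkage metrics.

The tumour burden of patient *i* (sum of longest target-lesion diameters,
mm) is modelled as the sum of an exponentially decaying treated fraction and
a linearly regrowing resistant fraction::

    TS_i(t) = BASE_i * exp(-SR_i * t) + PR_i * t        (t in days)

Individual parameters (BASE_i, SR_i, PR_i) are lognormally distributed
around population log-means theta with between-patient SDs omega, and the
observation likelihood is lognormal with residual log-SD sigma.  The
posterior is explored with a blocked Metropolis-within-Gibbs sampler:
population log-means get conjugate Gibbs updates, individual log-parameters
get vectorised per-patient random-walk Metropolis updates, and the SD
parameters get adaptive log-scale Metropolis updates.

Derived shrinkage metrics:

* PTR(w) = (BASE - TS(7w)) / BASE, the model-predicted fractional tumour
  reduction at week w (positive = shrinkage), computed from posterior-mean
  individual parameters;
* PTR_max, the best *observed* fractional reduction from baseline within a
  12-week window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SamplerConfig, TSPopulationParams, WEEK_DAYS
from .samplers import DiagnosticError, rhat_table

__all__ = [
    "IndividualKinetics",
    "TSPosterior",
    "ConvergenceReport",
    "predict_ts",
    "compute_ptr",
    "compute_ptr_max",
    "filter_evaluable",
    "fit_hierarchical",
    "fit_individual",
    "check_convergence",
    "ptr_metrics_table",
]

PTR_WEEKS = (2, 4, 6, 8, 10)
PTR_MAX_WINDOW_WEEKS = 12.0

# diffuse priors for the hierarchical fit
_PRIOR_THETA_SD = 10.0
_PRIOR_OMEGA_SCALE = 5.0  # half-normal on omegas and sigma


class DataError(ValueError):
    """Raised for invalid tumour-size input data."""


@dataclass(frozen=True)
class IndividualKinetics:
    """Per-patient kinetic parameters: BASE (mm), SR (1/day), PR (mm/day)."""

    base: float
    sr: float
    pr: float

    def __post_init__(self) -> None:
        # zero rates are the degenerate no-dynamics limit of the lognormal
        # individual distributions; a non-positive baseline is never valid
        if not (self.base > 0 and self.sr >= 0 and self.pr >= 0):
            raise DataError("BASE must be positive and rates non-negative")


def predict_ts(kinetics: IndividualKinetics, t_days) -> np.ndarray | float:
    """Model tumour size (mm) at time ``t_days`` >= 0."""
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise DataError("time must be non-negative")
    out = kinetics.base * np.exp(-kinetics.sr * t) + kinetics.pr * t
    return float(out) if out.ndim == 0 else out


def compute_ptr(kinetics: IndividualKinetics, week: float) -> float:
    """Fractional tumour reduction from baseline at ``week`` (positive = shrinkage)."""
    if week <= 0:
        raise DataError("week must be positive")
    t = week * WEEK_DAYS
    return 1.0 - predict_ts(kinetics, t) / kinetics.base


def compute_ptr_max(series: pd.DataFrame, window_weeks: float = PTR_MAX_WINDOW_WEEKS) -> float:
    """Best observed fractional reduction from baseline within the window.

    ``series`` holds one patient's scans (columns ``time_weeks``, ``ts_mm``).
    Uses observed sizes only.  Returns NaN when there is no on-treatment scan
    inside ``(0, window_weeks]`` — the metric is then undefined, not zero.
    """
    t = series["time_weeks"].to_numpy(dtype=float)
    y = series["ts_mm"].to_numpy(dtype=float)
    base_mask = t == 0
    if not base_mask.any():
        raise DataError("series has no baseline (time 0) scan")
    y0 = float(y[base_mask][0])
    in_window = (t > 0) & (t <= window_weeks)
    if not in_window.any():
        return float("nan")
    return float(np.max((y0 - y[in_window]) / y0))


def filter_evaluable(ts_series: pd.DataFrame) -> list:
    """Patients with a pre-treatment scan and at least one on-treatment scan."""
    t = ts_series["time_weeks"].to_numpy(dtype=float)
    if np.any(t < 0):
        raise DataError("scan times must be non-negative")
    has_base = ts_series[t == 0].groupby("patient_id").size()
    has_ontx = ts_series[t > 0].groupby("patient_id").size()
    ids = sorted(set(has_base.index) & set(has_ontx.index))
    return ids


# ---------------------------------------------------------------------------
# hierarchical fit
# ---------------------------------------------------------------------------


@dataclass
class TSPosterior:
    """Posterior draws of the hierarchical tumour-size model.

    ``pop_draws`` maps each population parameter name to a (chains, iters)
    array; ``indiv_draws`` maps "log_base"/"log_sr"/"log_pr" to
    (chains, iters, n_patients) arrays.  ``individual_means`` holds
    posterior-mean BASE/SR/PR per patient (natural scale).
    """

    pop_draws: dict[str, np.ndarray]
    indiv_draws: dict[str, np.ndarray]
    patient_ids: list
    rhat: dict[str, float] = field(default_factory=dict)
    individual_means: pd.DataFrame | None = None
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        arr = next(iter(self.pop_draws.values()))
        return arr.shape[0] * arr.shape[1]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.pop_draws.items():
            rows.append(
                {
                    "parameter": name,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)),
                    "q2.5": float(np.quantile(arr, 0.025)),
                    "q97.5": float(np.quantile(arr, 0.975)),
                    "rhat": self.rhat.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class ConvergenceReport:
    passed: bool
    threshold: float
    max_rhat: float
    offenders: tuple[str, ...]


def check_convergence(posterior: TSPosterior, threshold: float = 1.1) -> ConvergenceReport:
    """Split-R-hat on every sampled quantity; pass iff all < threshold."""
    some = next(iter(posterior.pop_draws.values()))
    if some.shape[0] < 2:
        raise DiagnosticError("convergence check needs at least 2 chains")
    rhats = dict(posterior.rhat)
    finite = {k: v for k, v in rhats.items() if np.isfinite(v)}
    offenders = tuple(k for k, v in finite.items() if v >= threshold)
    max_rhat = max(finite.values()) if finite else float("nan")
    return ConvergenceReport(
        passed=len(offenders) == 0, threshold=threshold, max_rhat=max_rhat, offenders=offenders
    )


def _pad_series(ts_series: pd.DataFrame, patient_ids: list):
    """Pack per-patient scans into padded (n, m) arrays of days and log-sizes."""
    groups = {pid: g for pid, g in ts_series.groupby("patient_id")}
    n = len(patient_ids)
    m = max(len(groups[pid]) for pid in patient_ids)
    t_days = np.zeros((n, m))
    logy = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    for i, pid in enumerate(patient_ids):
        g = groups[pid].sort_values("time_weeks")
        y = g["ts_mm"].to_numpy(dtype=float)
        if np.any(y <= 0):
            raise DataError(f"non-positive tumour size for patient {pid}")
        k = len(g)
        t_days[i, :k] = g["time_weeks"].to_numpy(dtype=float) * WEEK_DAYS
        logy[i, :k] = np.log(y)
        mask[i, :k] = True
    return t_days, logy, mask


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2


def fit_hierarchical(
    ts_series: pd.DataFrame,
    sampler: SamplerConfig | None = None,
) -> TSPosterior:
    """Fit the three-stage hierarchical tumour-size model by MCMC.

    Only evaluable patients (baseline + >=1 on-treatment scan) enter the
    fit.  Population log-means use conjugate Gibbs steps; individual
    log-parameters and the SDs use adaptive random-walk Metropolis, with
    step sizes frozen after warm-up.
    """
    sampler = sampler or SamplerConfig()
    ids = filter_evaluable(ts_series)
    if len(ids) < 2:
        raise DataError("hierarchical fit needs at least 2 evaluable patients")
    ts_series = ts_series[ts_series["patient_id"].isin(ids)]
    t_days, logy, mask = _pad_series(ts_series, ids)
    n = len(ids)
    nobs = mask.sum(axis=1)

    chains, warmup, iters, thin = sampler.chains, sampler.warmup, sampler.iters, sampler.thin
    pop_names = ["theta_base", "theta_sr", "theta_pr", "omega_base", "omega_sr", "omega_pr", "sigma_ts"]
    pop_store = {k: np.empty((chains, iters)) for k in pop_names}
    ind_store = {k: np.empty((chains, iters, n)) for k in ("log_base", "log_sr", "log_pr")}
    acc_tot = {"b": 0.0, "s": 0.0, "p": 0.0}

    # data-driven starting points: baseline log-size from the first scan,
    # generic per-day rates for decay/regrowth
    first_idx = np.argmax(mask, axis=1)
    b_init = logy[np.arange(n), first_idx]

    for c in range(chains):
        rng = np.random.default_rng((sampler.seed, c))
        b = b_init + 0.05 * rng.standard_normal(n)
        s = -6.5 + 0.3 * rng.standard_normal(n)
        p = -3.5 + 0.3 * rng.standard_normal(n)
        th = np.array([b.mean(), s.mean(), p.mean()])
        om = np.array([0.5, 0.8, 0.8])
        sigma = 0.2

        # cached model pieces: decay basis E, growth term G, per-patient SSR
        E = np.exp(-np.exp(s)[:, None] * t_days)
        G = np.exp(p)[:, None] * t_days
        f = np.exp(b)[:, None] * E + G
        resid = np.where(mask, logy - np.log(f), 0.0)
        ssr = (resid**2).sum(axis=1)

        step_b = np.full(n, 0.05)
        step_s = np.full(n, 0.4)
        step_p = np.full(n, 0.4)
        step_sp = np.full(n, 0.4)  # joint anti-correlated (SR, PR) direction
        step_om = np.full(3, 0.3)
        step_sig = 0.1

        total = warmup + iters * thin
        for it in range(total):
            adapting = it < warmup
            gamma = (it + 1) ** -0.6 if adapting else 0.0
            inv2s2 = 1.0 / (2.0 * sigma**2)

            # --- individual parameter blocks (vectorised across patients) ---
            for comp in ("b", "s", "p"):
                if comp == "b":
                    prop = b + step_b * rng.standard_normal(n)
                    f_new = np.exp(prop)[:, None] * E + G
                    cur, theta_k, omega_k = b, th[0], om[0]
                elif comp == "s":
                    prop = s + step_s * rng.standard_normal(n)
                    E_new = np.exp(-np.exp(prop)[:, None] * t_days)
                    f_new = np.exp(b)[:, None] * E_new + G
                    cur, theta_k, omega_k = s, th[1], om[1]
                else:
                    prop = p + step_p * rng.standard_normal(n)
                    G_new = np.exp(prop)[:, None] * t_days
                    f_new = np.exp(b)[:, None] * E + G_new
                    cur, theta_k, omega_k = p, th[2], om[2]
                resid_new = np.where(mask, logy - np.log(f_new), 0.0)
                ssr_new = (resid_new**2).sum(axis=1)
                dlp = (
                    (ssr - ssr_new) * inv2s2
                    + ((cur - theta_k) ** 2 - (prop - theta_k) ** 2) / (2.0 * omega_k**2)
                )
                accept = np.log(rng.uniform(size=n)) < dlp
                if comp == "b":
                    b = np.where(accept, prop, b)
                elif comp == "s":
                    s = np.where(accept, prop, s)
                    E = np.where(accept[:, None], E_new, E)
                else:
                    p = np.where(accept, prop, p)
                    G = np.where(accept[:, None], G_new, G)
                ssr = np.where(accept, ssr_new, ssr)
                if adapting:
                    delta = gamma * (accept.astype(float) - 0.44)
                    if comp == "b":
                        step_b *= np.exp(delta)
                    elif comp == "s":
                        step_s *= np.exp(delta)
                    else:
                        step_p *= np.exp(delta)
                elif it >= warmup:
                    acc_tot[comp] += accept.mean()

            # --- joint (SR, PR) move along their trade-off direction: for
            # sparsely scanned patients the likelihood is nearly flat when a
            # faster decay is offset by faster regrowth ---
            d = step_sp * rng.standard_normal(n)
            s_prop, p_prop = s + d, p - d
            E_new = np.exp(-np.exp(s_prop)[:, None] * t_days)
            G_new = np.exp(p_prop)[:, None] * t_days
            f_new = np.exp(b)[:, None] * E_new + G_new
            resid_new = np.where(mask, logy - np.log(f_new), 0.0)
            ssr_new = (resid_new**2).sum(axis=1)
            dlp = (
                (ssr - ssr_new) * inv2s2
                + ((s - th[1]) ** 2 - (s_prop - th[1]) ** 2) / (2.0 * om[1] ** 2)
                + ((p - th[2]) ** 2 - (p_prop - th[2]) ** 2) / (2.0 * om[2] ** 2)
            )
            accept = np.log(rng.uniform(size=n)) < dlp
            s = np.where(accept, s_prop, s)
            p = np.where(accept, p_prop, p)
            E = np.where(accept[:, None], E_new, E)
            G = np.where(accept[:, None], G_new, G)
            ssr = np.where(accept, ssr_new, ssr)
            if adapting:
                step_sp *= np.exp(gamma * (accept.astype(float) - 0.44))

            # --- population log-means: conjugate normal Gibbs ---
            for k, x in enumerate((b, s, p)):
                prec = n / om[k] ** 2 + 1.0 / _PRIOR_THETA_SD**2
                mu_post = (x.sum() / om[k] ** 2) / prec
                th[k] = mu_post + rng.standard_normal() / np.sqrt(prec)

            # --- between-patient SDs: log-scale Metropolis ---
            for k, x in enumerate((b, s, p)):
                om_new = om[k] * np.exp(step_om[k] * rng.standard_normal())
                sq = ((x - th[k]) ** 2).sum()
                lp_cur = -n * np.log(om[k]) - sq / (2 * om[k] ** 2) + _halfnormal_logpdf(om[k], _PRIOR_OMEGA_SCALE) + np.log(om[k])
                lp_new = -n * np.log(om_new) - sq / (2 * om_new**2) + _halfnormal_logpdf(om_new, _PRIOR_OMEGA_SCALE) + np.log(om_new)
                if np.log(rng.uniform()) < lp_new - lp_cur:
                    om[k] = om_new
                    if adapting:
                        step_om[k] *= np.exp(gamma * (1.0 - 0.44))
                elif adapting:
                    step_om[k] *= np.exp(gamma * (0.0 - 0.44))

            # --- residual SD: log-scale Metropolis using cached SSR ---
            sig_new = sigma * np.exp(step_sig * rng.standard_normal())
            ntot = nobs.sum()
            ssr_tot = ssr.sum()
            lp_cur = -ntot * np.log(sigma) - ssr_tot / (2 * sigma**2) + _halfnormal_logpdf(sigma, _PRIOR_OMEGA_SCALE) + np.log(sigma)
            lp_new = -ntot * np.log(sig_new) - ssr_tot / (2 * sig_new**2) + _halfnormal_logpdf(sig_new, _PRIOR_OMEGA_SCALE) + np.log(sig_new)
            if np.log(rng.uniform()) < lp_new - lp_cur:
                sigma = sig_new
                if adapting:
                    step_sig *= np.exp(gamma * (1.0 - 0.44))
            elif adapting:
                step_sig *= np.exp(gamma * (0.0 - 0.44))

            if not adapting:
                k = it - warmup
                if (k + 1) % thin == 0:
                    j = k // thin
                    for name, val in zip(pop_names, (*th, *om, sigma)):
                        pop_store[name][c, j] = val
                    ind_store["log_base"][c, j] = b
                    ind_store["log_sr"][c, j] = s
                    ind_store["log_pr"][c, j] = p

    rhats = rhat_table({**pop_store, **ind_store})
    individual_means = pd.DataFrame(
        {
            "BASE": np.exp(ind_store["log_base"]).mean(axis=(0, 1)),
            "SR": np.exp(ind_store["log_sr"]).mean(axis=(0, 1)),
            "PR": np.exp(ind_store["log_pr"]).mean(axis=(0, 1)),
        },
        index=pd.Index(ids, name="patient_id"),
    )
    denom = chains * iters * thin
    return TSPosterior(
        pop_draws=pop_store,
        indiv_draws=ind_store,
        patient_ids=list(ids),
        rhat=rhats,
        individual_means=individual_means,
        accept_rates={k: v / denom for k, v in acc_tot.items()},
    )


def fit_individual(
    series: pd.DataFrame,
    pop: TSPopulationParams,
    sampler: SamplerConfig | None = None,
    sigma_ts: float | None = None,
) -> tuple[IndividualKinetics, np.ndarray]:
    """Posterior for one patient's kinetics with the population as fixed prior.

    Useful for interpolating a new patient without refitting the hierarchy.
    Returns posterior-mean kinetics and the (chains, iters, 3) draws of the
    log-parameters.
    """
    from .samplers import adaptive_metropolis

    sampler = sampler or SamplerConfig(warmup=1500, iters=500, thin=5)
    sigma = pop.sigma_ts if sigma_ts is None else sigma_ts
    t = series["time_weeks"].to_numpy(dtype=float) * WEEK_DAYS
    y = series["ts_mm"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise DataError("non-positive tumour size")
    logy = np.log(y)
    thetas = np.array(pop.thetas)
    omegas = np.array(pop.omegas)

    def log_post(x: np.ndarray) -> float:
        bb, ss, pp = x
        f = np.exp(bb) * np.exp(-np.exp(ss) * t) + np.exp(pp) * t
        ll = -0.5 * np.sum(((logy - np.log(f)) / sigma) ** 2)
        lp = -0.5 * np.sum(((x - thetas) / omegas) ** 2)
        return float(ll + lp)

    x0 = np.array([np.log(y[0]), pop.theta_sr, pop.theta_pr])
    res = adaptive_metropolis(
        log_post, x0, chains=sampler.chains, warmup=sampler.warmup,
        iters=sampler.iters, thin=sampler.thin, seed=sampler.seed,
    )
    means = np.exp(res.draws.reshape(-1, 3)).mean(axis=0)
    return IndividualKinetics(*means), res.draws


def ptr_metrics_table(
    individual_means: pd.DataFrame,
    ts_series: pd.DataFrame,
    weeks: tuple[int, ...] = PTR_WEEKS,
    window_weeks: float = PTR_MAX_WINDOW_WEEKS,
) -> pd.DataFrame:
    """Model-derived PTR at the requested weeks plus observed PTR_max.

    One row per evaluable patient; PTR values are fractions (0.01 = 1 %).
    """
    ids = filter_evaluable(ts_series)
    rows = {}
    groups = dict(tuple(ts_series.groupby("patient_id")))
    for pid in ids:
        k = IndividualKinetics(*individual_means.loc[pid, ["BASE", "SR", "PR"]])
        row = {f"PTR_wk{w}": compute_ptr(k, w) for w in weeks}
        row["PTR_max"] = compute_ptr_max(groups[pid], window_weeks)
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "patient_id"
    return out
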