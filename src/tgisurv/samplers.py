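"""Generic MCMC building blocks: split-R-hat and an adaptive Metropolis sampler.

The adaptive random-walk Metropolis sampler is used for the low-dimensional
accelerated-failure-time posteriors; the hierarchical tumour-size model has
its own blocked sampler in :mod:`tgisurv.kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


class DiagnosticError(ValueError):
    """Raised when a convergence diagnostic cannot be computed."""


def split_rhat(draws: np.ndarray) -> float:
    """Potential scale reduction of a (chains, iters) draw array.

    Each chain is split in half, so convergence failures *within* a chain
    (trends) inflate the statistic as well as disagreement between chains.
    Returns NaN for a constant quantity (zero variance everywhere).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise DiagnosticError("draws must be a (chains, iters) array")
    n_chains, n_iter = draws.shape
    if n_chains < 2:
        raise DiagnosticError("split-R-hat needs at least 2 chains")
    if n_iter < 4:
        raise DiagnosticError("split-R-hat needs at least 4 iterations per chain")
    half = n_iter // 2
    # drop a trailing draw if the chain length is odd
    segments = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = segments.shape
    chain_means = segments.mean(axis=1)
    chain_vars = segments.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        return float("nan") if b == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def rhat_table(draws: dict[str, np.ndarray]) -> dict[str, float]:
    """split-R-hat for every entry of a name -> (chains, iters[, k]) dict."""
    out: dict[str, float] = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            out[name] = split_rhat(arr)
        elif arr.ndim == 3:
            for k in range(arr.shape[2]):
                out[f"{name}[{k}]"] = split_rhat(arr[:, :, k])
        else:
            raise DiagnosticError(f"unsupported draw shape for {name}: {arr.shape}")
    return out


@dataclass
class MHResult:
    """Draws (chains, iters, dim) plus acceptance rates per chain."""

    draws: np.ndarray
    accept_rate: np.ndarray


def adaptive_metropolis(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    *,
    chains: int = 4,
    warmup: int = 1000,
    iters: int = 500,
    thin: int = 5,
    seed: int = 0,
    jitter: float = 0.1,
    init_cov: np.ndarray | None = None,
) -> MHResult:
    """Random-walk Metropolis with Haario-style covariance adaptation.

    During warm-up the proposal covariance is adapted to the running sample
    covariance (scaled by 2.38^2/d) and a global step-size multiplier is
    tuned toward a ~30 % acceptance rate; both are frozen afterwards so the
    retained draws target the exact posterior.  ``init_cov`` (e.g. a Laplace
    approximation) preconditions the proposal before adaptation has data.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    rng = np.random.default_rng(seed)
    draws = np.empty((chains, iters, d))
    acc_rates = np.empty(chains)
    target_acc = 0.30 if d > 1 else 0.44
    if init_cov is not None:
        init_chol = np.linalg.cholesky((2.38**2 / d) * init_cov + 1e-12 * np.eye(d))
        jitter_vec = np.sqrt(np.diag(init_cov))
    else:
        init_chol = np.linalg.cholesky(np.eye(d) * 0.01)
        jitter_vec = np.full(d, jitter)

    for c in range(chains):
        x = x0 + jitter_vec * rng.standard_normal(d)
        lp = log_post(x)
        # fall back to the unjittered start if the jitter left the support
        if not np.isfinite(lp):
            x = x0.copy()
            lp = log_post(x)
        if not np.isfinite(lp):
            raise ValueError("log posterior not finite at the initial point")
        log_scale = 0.0
        chol = init_chol.copy()
        mean = x.copy()
        m2 = np.zeros((d, d))
        n_seen = 0
        n_acc = 0
        n_prop = 0
        total = warmup + iters * thin
        for it in range(total):
            adapting = it < warmup
            step = np.exp(log_scale) * (chol @ rng.standard_normal(d))
            x_new = x + step
            lp_new = log_post(x_new)
            accept = np.log(rng.uniform()) < lp_new - lp
            if accept:
                x, lp = x_new, lp_new
            if adapting:
                gamma = (it + 1) ** -0.6
                log_scale += gamma * (float(accept) - target_acc)
                n_seen += 1
                delta = x - mean
                mean += delta / n_seen
                m2 += np.outer(delta, x - mean)
                if n_seen > 2 * d and (it + 1) % 50 == 0:
                    samp_cov = m2 / (n_seen - 1)
                    samp_cov = (2.38**2 / d) * samp_cov + 1e-10 * np.eye(d)
                    try:
                        chol = np.linalg.cholesky(samp_cov)
                    except np.linalg.LinAlgError:
                        pass
            else:
                n_acc += int(accept)
                n_prop += 1
                k = it - warmup
                if (k + 1) % thin == 0:
                    draws[c, k // thin] = x
        acc_rates[c] = n_acc / max(n_prop, 1)
    return MHResult(draws=draws, accept_rate=acc_rates)
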