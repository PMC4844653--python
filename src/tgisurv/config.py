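"""Configuration objects shared across the pipeline.

Unit conventions
----------------
Tumour-size kinetics run on a *day* time scale (shrinkage rate SR in 1/day,
regrowth rate PR in mm/day); survival times, scan schedules and everything
reported to the user are in *weeks*.  Conversions happen explicitly at module
boundaries (``WEEK_DAYS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

WEEK_DAYS = 7.0

#: horizons used for time-dependent AUROC reporting: 3/6/9/12 months in weeks
DEFAULT_HORIZONS_WEEKS = (13.0, 26.0, 39.0, 52.0)


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class TSPopulationParams:
    """Population-level parameters of the tumour-size kinetic model.

    ``theta_*`` are means of the log-transformed individual parameters,
    ``omega_*`` the between-patient SDs on the log scale, and ``sigma_ts``
    the residual SD of log tumour size.  Defaults are posterior means
    estimated on a gemcitabine-treated metastatic pancreatic cancer cohort
    (baseline size ~97.5 mm, shrinkage rate ~1.14e-3/day, regrowth
    ~4.2e-2 mm/day).
    """

    theta_base: float = 4.58
    theta_sr: float = -6.78
    theta_pr: float = -3.17
    omega_base: float = 0.648
    omega_sr: float = 1.32
    omega_pr: float = 0.835
    sigma_ts: float = 0.150

    def __post_init__(self) -> None:
        # zero disables the corresponding variability (noise-free simulation);
        # fitted posteriors are always strictly positive
        for name in ("omega_base", "omega_sr", "omega_pr", "sigma_ts"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def thetas(self) -> tuple[float, float, float]:
        return (self.theta_base, self.theta_sr, self.theta_pr)

    @property
    def omegas(self) -> tuple[float, float, float]:
        return (self.omega_base, self.omega_sr, self.omega_pr)


@dataclass(frozen=True)
class AFTParams:
    """Parameters of a parametric accelerated-failure-time survival model.

    dist
        ``"lognormal"``: log T ~ Normal(mu, sigma_ln) with
        mu = exp(theta0) + sum(theta_x * x_centered) by default, or
        mu = exp(theta0 + sum(theta_x * x_centered)) when ``log_linear``.
        The linear-in-mu default makes the ratio of median survival times
        (acceleration factor) exactly exp(theta_x * delta).
        ``"weibull"``: S(t) = exp(-(t/lam)^alpha) with
        lam = exp(theta0 + sum(theta_x * x_centered)).
    coeffs / centers
        Per-covariate coefficient theta_x and the centering constant that
        was subtracted from the raw covariate before multiplying.
    """

    dist: str = "lognormal"
    theta0: float = 1.25
    coeffs: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)
    sigma_ln: float | None = 0.544
    alpha: float | None = None
    log_linear: bool = False

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "weibull"):
            raise ConfigurationError(f"unknown survival distribution {self.dist!r}")
        if self.dist == "lognormal":
            if self.sigma_ln is None or self.sigma_ln <= 0:
                raise ConfigurationError("lognormal AFT needs sigma_ln > 0")
        else:
            if self.alpha is None or self.alpha <= 0:
                raise ConfigurationError("Weibull AFT needs shape alpha > 0")

    def center_for(self, name: str) -> float:
        return self.centers.get(name, 0.0)

    def with_centers(self, centers: dict[str, float]) -> "AFTParams":
        return replace(self, centers=dict(centers))


#: default survival-model truth for cohort simulation: a lognormal AFT in
#: which larger baseline tumours shorten survival, early fractional tumour
#: shrinkage (PTR at week 2, as a fraction) and higher albumin lengthen it.
def default_aft_truth() -> AFTParams:
    return AFTParams(
        dist="lognormal",
        theta0=1.25,
        coeffs={"TS0": -0.001, "PTR_wk2": 1.07, "ALB": 0.0079},
        centers={},  # filled with cohort medians at simulation time
        sigma_ln=0.544,
    )


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution descriptor for one baseline covariate.

    kind is ``"normal"``, ``"lognormal"`` (location/spread on the log scale)
    or ``"bernoulli"`` (location = success probability).  Continuous draws
    are clipped to [lower, upper] when given.
    """

    name: str
    kind: str
    location: float
    spread: float = 0.0
    lower: float | None = None
    upper: float | None = None
    log_transform: bool = False  # log-transform before screening/regression

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "lognormal", "bernoulli"):
            raise ConfigurationError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "bernoulli" and not 0.0 <= self.location <= 1.0:
            raise ConfigurationError(f"{self.name}: bernoulli probability outside [0, 1]")
        if self.kind != "bernoulli" and self.spread < 0:
            raise ConfigurationError(f"{self.name}: spread must be non-negative")


def default_covariate_specs() -> tuple[CovariateSpec, ...]:
    """Baseline covariates of a metastatic pancreatic cancer cohort.

    Locations/spreads chosen so that cohort medians and ranges match a
    gemcitabine control arm: ALB 41 G/l (26-62), ALP 161 IU/l, BSA 1.78 m2,
    BILI 10.3 umol/l, CA19-9 1426 IU/ml, NEUT 5.75 G/l, TS0 107 mm; ECOG
    1-or-2 in 63 %, tumour in pancreas body/tail in 32 %, diabetes in 32 %.
    ALP, CA19-9 and NEUT are heavily right-skewed and flagged for
    log-transformation before regression.
    """
    import math

    return (
        CovariateSpec("ALB", "normal", 41.0, 6.0, 26.0, 62.0),
        CovariateSpec("ALP", "lognormal", math.log(161.0), 1.0, 5.04, 1686.0, log_transform=True),
        CovariateSpec("BSA", "normal", 1.78, 0.16, 1.31, 2.29),
        CovariateSpec("BILI", "lognormal", math.log(10.3), 0.55, 1.71, 34.4),
        CovariateSpec("CA19_9", "lognormal", math.log(1426.0), 2.2, 0.6, 294800.0, log_transform=True),
        CovariateSpec("NEUT", "lognormal", math.log(5.75), 0.5, 1.55, 34.7, log_transform=True),
        CovariateSpec("TS0", "lognormal", math.log(107.0), 0.648, 19.0, 378.0),
        CovariateSpec("ECOG", "bernoulli", 0.63),   # 1 = performance status 1 or 2
        CovariateSpec("CLOC", "bernoulli", 0.32),   # 1 = pancreas body or tail
        CovariateSpec("DIAB", "bernoulli", 0.32),   # 1 = diabetic
    )


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to simulate one cohort."""

    n_patients: int = 120
    seed: int = 0
    ts_pop_params: TSPopulationParams = field(default_factory=TSPopulationParams)
    aft_truth: AFTParams = field(default_factory=default_aft_truth)
    assessment_interval: float = 8.0   # weeks between scans
    max_followup: float = 69.0         # weeks, administrative censoring
    covariate_specs: tuple[CovariateSpec, ...] = field(default_factory=default_covariate_specs)
    p_no_scans: float = 0.0            # probability of no on-treatment scan
    missing_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.assessment_interval <= 0:
            raise ConfigurationError("assessment_interval must be > 0")
        if self.max_followup <= 0:
            raise ConfigurationError("max_followup must be > 0")
        if not 0.0 <= self.p_no_scans <= 1.0:
            raise ConfigurationError("p_no_scans must be a probability")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"missing rate for {name} must be in [0, 1)")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings: 4 chains x 500 retained draws after warm-up by default.

    ``thin`` spaces the retained draws to cut autocorrelation of the
    random-walk kernels; the retained draw count is ``iters`` regardless.
    """

    chains: int = 4
    warmup: int = 1500
    iters: int = 500
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.iters < 1 or self.thin < 1:
            raise ConfigurationError("invalid sampler configuration")
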