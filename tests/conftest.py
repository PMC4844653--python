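import numpy as np
import pandas as pd
import pytest

from tgisurv import CohortConfig, SamplerConfig, TSPopulationParams, generate_cohort
from tgisurv.kinetics import IndividualKinetics


@pytest.fixture(scope="session")
def pop_truth() -> TSPopulationParams:
    """Population kinetic truth used throughout (training-cohort posterior means)."""
    return TSPopulationParams()


@pytest.fixture(scope="session")
def typical_kinetics(pop_truth) -> IndividualKinetics:
    """Kinetics of the typical patient: exponentials of the population log-means."""
    return IndividualKinetics(
        base=np.exp(pop_truth.theta_base),
        sr=np.exp(pop_truth.theta_sr),
        pr=np.exp(pop_truth.theta_pr),
    )


@pytest.fixture(scope="session")
def light_sampler() -> SamplerConfig:
    """Short chains for tests where speed matters more than tail accuracy."""
    return SamplerConfig(chains=2, warmup=600, iters=250, thin=4, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort with default (published-truth) generating values."""
    return generate_cohort(CohortConfig(n_patients=60, seed=3))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 150-patient cohort with a few scan-dropout patients."""
    return generate_cohort(CohortConfig(n_patients=150, seed=5, p_no_scans=0.05))


def make_records(times, events, ids=None) -> pd.DataFrame:
    idx = pd.Index(ids if ids is not None else range(len(times)), name="patient_id")
    return pd.DataFrame(
        {"time_weeks": np.asarray(times, dtype=float), "event": np.asarray(events, dtype=int)},
        index=idx,
    )


@pytest.fixture()
def toy_records() -> pd.DataFrame:
    """Six survival records with mixed censoring for hand computations."""
    return make_records([5, 8, 8, 12, 16, 20], [1, 1, 0, 1, 0, 1])
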