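"""Reading and writing the pipeline's on-disk formats (CSV + JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SyntheticCohort

__all__ = ["write_cohort", "read_cohort_dir", "to_jsonable", "write_report"]


def to_jsonable(obj):
    """Recursively convert numpy/pandas/dataclass objects to JSON types."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return to_jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return to_jsonable(obj.reset_index().to_dict(orient="records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_cohort(directory: str | Path, cohort: SyntheticCohort) -> None:
    """Write cohort.csv, ts.csv, survival.csv and truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.covariates.to_csv(d / "cohort.csv")
    cohort.ts_series.to_csv(d / "ts.csv", index=False)
    cohort.survival.to_csv(d / "survival.csv")
    truth = {
        "pop_params": dataclasses.asdict(cohort.truth["pop_params"]),
        "aft_params": dataclasses.asdict(cohort.truth["aft_params"]),
        "kinetics": to_jsonable(cohort.truth["kinetics"]),
        "death_times_weeks": to_jsonable(cohort.truth["death_times_weeks"]),
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort_dir(directory: str | Path):
    """Load (covariates, ts_series, survival) frames from a cohort directory."""
    d = Path(directory)
    cov = pd.read_csv(d / "cohort.csv", index_col="patient_id")
    ts = pd.read_csv(d / "ts.csv")
    surv = pd.read_csv(d / "survival.csv", index_col="patient_id")
    return cov, ts, surv


def write_report(path: str | Path, report: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(to_jsonable(report), indent=1))
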