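"""Landmark dataset construction and stacking.

At each landmark age L the registry is restricted to individuals known to
be alive, untransplanted, diagnosed and under registry observation at L
(with the age-L date inside the study window).  Covariate histories are
summarized by last observation carried forward (LOCF), the residual
survival outcome is measured from L with administrative censoring at the
horizon L + w, and the per-landmark datasets are stacked into a single
dataset for supermodel fitting.

Conventions (documented choices where the construction rules leave room):

* a death exactly at L makes the patient ineligible (not "alive at" L);
  a death exactly at L + w counts as an event with time = w;
* a transplant at or before L excludes the patient from the age-L dataset;
  deaths after a post-L transplant count as events;
* there is no staleness limit on LOCF values, but the lag (years since the
  most recent measurement of each variable) is recorded for diagnostics;
* calendar year enters as a continuous covariate (the patient's decimal
  calendar year at age L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic_registry import (
    BASELINE_VARIABLES,
    TIME_DEPENDENT_VARIABLES,
    Registry,
)

__all__ = [
    "LandmarkDataset",
    "StackedDataset",
    "MissingHistoryError",
    "build_landmark_dataset",
    "build_stacked_dataset",
    "locf_covariates",
    "stack",
    "default_landmark_grid",
    "DEFAULT_PREDICTORS",
    "write_stacked",
    "read_stacked",
]

#: Default predictor columns of a landmark record: three baseline variables,
#: calendar year at the landmark age, and the 13 LOCF time-dependent values.
DEFAULT_PREDICTORS: Tuple[str, ...] = BASELINE_VARIABLES + ("calendar_year",) + TIME_DEPENDENT_VARIABLES


def default_landmark_grid(start: int = 18, stop: int = 50, step: int = 1) -> List[int]:
    """Integer landmark ages, by default 18..50 inclusive (33 ages)."""
    return list(range(start, stop + 1, step))


class MissingHistoryError(ValueError):
    """No pre-landmark measurement exists for a required variable."""


@dataclass
class LandmarkDataset:
    """Records of one landmark age: one row per eligible patient."""

    L: float
    records: pd.DataFrame
    exclusion_log: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class StackedDataset:
    """Union of landmark datasets; a patient may appear at many landmark ages."""

    records: pd.DataFrame
    landmark_grid: List[float]

    def __len__(self) -> int:
        return len(self.records)


_EXCLUSION_REASONS = (
    "outside_study_window",
    "dead_before_L",
    "lost_before_L",
    "transplant_before_L",
    "diagnosed_after_L",
    "entry_after_L",
    "missing_covariate_history",
    "zero_followup",
)


def locf_covariates(
    reviews_of_patient: pd.DataFrame,
    L: float,
    variables: Sequence[str] = TIME_DEPENDENT_VARIABLES,
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """LOCF summary of one patient's reviews at landmark age L.

    For each variable, returns the value at the latest review with
    ``age <= L`` at which that variable was recorded, and the lag
    ``L - age`` of that review.  Raises :class:`MissingHistoryError` if some
    variable has no qualifying measurement.
    """
    pre = reviews_of_patient[reviews_of_patient["age"] <= L]
    values: Dict[str, float] = {}
    lags: Dict[str, float] = {}
    for v in variables:
        obs = pre[["age", v]].dropna()
        if obs.empty:
            raise MissingHistoryError(f"no measurement of '{v}' at or before age {L}")
        row = obs.iloc[obs["age"].values.argmax()]
        values[v] = float(row[v])
        lags[v] = float(L - row["age"])
    return values, lags


def build_landmark_dataset(
    registry: Registry,
    L: float,
    w: float = 10.0,
    study_window: Optional[Tuple[float, float]] = None,
    variables: Sequence[str] = TIME_DEPENDENT_VARIABLES,
    impute_missing: bool = False,
) -> LandmarkDataset:
    """Construct the landmark dataset at age ``L`` with horizon ``w``.

    Eligibility requires the patient's age-L date to fall inside the study
    window, survival and registry observation up to L, no transplant at or
    before L, diagnosis and registry entry by L, and an available LOCF
    history for every required variable (unless ``impute_missing``, in
    which case missing LOCF values are filled with the eligible-cohort
    mean).  The outcome is ``time = min(death, loss, study end, L + w) - L``
    with ``event = 1`` iff death occurs by that minimum.
    """
    if w <= 0:
        raise ValueError("horizon w must be > 0")
    if study_window is None:
        if registry.config_echo is None:
            raise ValueError("study_window must be given when the registry has no config")
        study_window = registry.config_echo.study_window
    start_year, end_year = study_window

    pats = registry.patients
    log = {k: 0 for k in _EXCLUSION_REASONS}
    if len(pats) == 0:
        return LandmarkDataset(L=L, records=_empty_records(variables), exclusion_log=log)

    age_L_year = pats["birth"].values + L
    death = pats["death_age"].values
    loss = pats["loss_age"].values
    tx = pats["transplant_age"].values

    in_window = (age_L_year >= start_year) & (age_L_year <= end_year)
    alive = ~(death <= L)  # NaN-safe: NaN comparisons are False
    not_lost = ~(loss <= L)
    untransplanted = ~(tx <= L)
    diagnosed = pats["diagnosis_age"].values <= L
    entered = pats["registry_entry_age"].values <= L

    eligible = np.ones(len(pats), dtype=bool)
    for reason, mask in (
        ("outside_study_window", in_window),
        ("dead_before_L", alive),
        ("lost_before_L", not_lost),
        ("transplant_before_L", untransplanted),
        ("diagnosed_after_L", diagnosed),
        ("entry_after_L", entered),
    ):
        newly = eligible & ~mask
        log[reason] += int(newly.sum())
        eligible &= mask

    elig = pats[eligible].copy()
    if elig.empty:
        return LandmarkDataset(L=L, records=_empty_records(variables), exclusion_log=log)

    # outcome: time since L, administratively censored at min(study end, L + w)
    age_end = end_year - elig["birth"].values
    death_e = elig["death_age"].values
    loss_e = elig["loss_age"].values
    stop = np.fmin(np.fmin(np.where(np.isnan(death_e), np.inf, death_e), np.where(np.isnan(loss_e), np.inf, loss_e)),
                   np.minimum(age_end, L + w))
    time = stop - L
    event = (~np.isnan(death_e)) & (death_e <= stop)

    # LOCF covariates, vectorized per variable via last non-null review <= L
    rev = registry.reviews
    pre = rev[rev["age"] <= L]
    pre = pre[pre["patient_id"].isin(elig["id"].values)]
    pre = pre.sort_values(["patient_id", "age"], kind="mergesort")
    locf_vals = {}
    locf_lags = {}
    for v in variables:
        obs = pre[["patient_id", "age", v]].dropna(subset=[v])
        last = obs.groupby("patient_id", sort=False).tail(1).set_index("patient_id")
        locf_vals[v] = last[v]
        locf_lags[v] = L - last["age"]

    records = pd.DataFrame(
        {
            "patient_id": elig["id"].values,
            "L": L,
            "time": time,
            "event": event.astype(int),
            "sex": elig["sex"].values,
            "genotype_class": elig["genotype_class"].values,
            "diagnosis_age": elig["diagnosis_age"].values,
            "calendar_year": elig["birth"].values + L,
        }
    ).set_index("patient_id", drop=False)
    for v in variables:
        records[v] = locf_vals[v].reindex(records.index)
        records[f"locf_lag_{v}"] = locf_lags[v].reindex(records.index)

    var_cols = list(variables)
    missing = records[var_cols].isna().any(axis=1)
    if impute_missing:
        for v in var_cols:
            records[v] = records[v].fillna(records[v].mean())
            records[f"locf_lag_{v}"] = records[f"locf_lag_{v}"].fillna(np.inf)
    else:
        log["missing_covariate_history"] += int(missing.sum())
        records = records[~missing]

    records = records.reset_index(drop=True)
    # drop zero-length observation windows (patient censored exactly at L)
    zero_fu = records["time"] <= 0
    log["zero_followup"] += int(zero_fu.sum())
    records = records[~zero_fu].reset_index(drop=True)
    return LandmarkDataset(L=L, records=records, exclusion_log=log)


def _empty_records(variables: Sequence[str]) -> pd.DataFrame:
    cols = ["patient_id", "L", "time", "event", "sex", "genotype_class", "diagnosis_age", "calendar_year"]
    cols += list(variables) + [f"locf_lag_{v}" for v in variables]
    return pd.DataFrame(columns=cols)


def stack(datasets: Sequence[LandmarkDataset]) -> StackedDataset:
    """Stack landmark datasets (distinct landmark ages) into one dataset."""
    Ls = [d.L for d in datasets]
    if len(set(Ls)) != len(Ls):
        raise ValueError("duplicate landmark ages in stack()")
    order = np.argsort(Ls)
    frames = [datasets[i].records for i in order if len(datasets[i].records)]
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = datasets[0].records.iloc[:0].copy() if datasets else _empty_records(TIME_DEPENDENT_VARIABLES)
    return StackedDataset(records=records, landmark_grid=sorted(Ls))


def build_stacked_dataset(
    registry: Registry,
    grid: Optional[Sequence[float]] = None,
    w: float = 10.0,
    study_window: Optional[Tuple[float, float]] = None,
    variables: Sequence[str] = TIME_DEPENDENT_VARIABLES,
    impute_missing: bool = False,
) -> StackedDataset:
    """Build and stack landmark datasets over a grid (default ages 18..50)."""
    if grid is None:
        grid = default_landmark_grid()
    datasets = [
        build_landmark_dataset(registry, L, w=w, study_window=study_window,
                               variables=variables, impute_missing=impute_missing)
        for L in grid
    ]
    return stack(datasets)


def write_stacked(stacked: StackedDataset, path) -> None:
    stacked.records.to_csv(path, index=False)


def read_stacked(path) -> StackedDataset:
    records = pd.read_csv(path, float_precision="round_trip")
    grid = sorted(records["L"].unique().tolist()) if len(records) else []
    return StackedDataset(records=records, landmark_grid=grid)
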