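"""Predictive-performance evaluation for dynamic survival prediction.

Discrimination is measured by a truncated Harrell concordance index at
each prediction horizon; prediction error by an inverse-probability-of-
censoring-weighted (IPCW) Brier score with the censoring distribution
estimated by Kaplan-Meier on the evaluation records of each landmark age;
percentage reduction in Brier score is reported against the per-landmark
Kaplan-Meier (covariate-free) prediction.  A Monte-Carlo cross-validation
loop and a patient-level 80/20 stratified split support honest model
comparison, and calibration tables compare decile-grouped predicted
survival probabilities with Kaplan-Meier "observed" probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .landmark import StackedDataset
from .survival import CoxFit, StepFunction, predict_survival_at

__all__ = [
    "UndefinedMetricError",
    "PerformanceReport",
    "CalibrationTable",
    "c_index",
    "brier_score",
    "percent_reduction",
    "kaplan_meier",
    "km_survival_at",
    "split_stacked",
    "monte_carlo_cv",
    "calibration_table",
    "evaluate_predictions",
    "evaluate_fit",
]

DEFAULT_HORIZONS: Tuple[float, ...] = (2.0, 5.0, 10.0)


class UndefinedMetricError(ValueError):
    """The metric is undefined on the given records (e.g. no evaluable pairs)."""


@dataclass
class PerformanceReport:
    """Per-landmark and pooled C-index / Brier / percent reduction."""

    per_landmark: pd.DataFrame
    overall: Dict[str, float]
    percent_reduction: Dict[float, float]
    cv_summary: Optional[pd.DataFrame] = None
    n_records: int = 0
    n_failures: int = 0


@dataclass
class CalibrationTable:
    """Decile-grouped predicted vs observed survival at one (L, horizon)."""

    horizon: float
    table: pd.DataFrame
    L: Optional[float] = None


# Kaplan-Meier ---------------------------------------------------------------


def kaplan_meier(time, event) -> StepFunction:
    """Product-limit estimator of the survival function S(t) = P(T > t)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if len(time) == 0:
        raise ValueError("kaplan_meier requires at least one observation")
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order]
    te = np.sort(t[e])
    ev_times = np.unique(te)
    n = len(t)
    at_risk = n - np.searchsorted(t, ev_times, side="left")
    deaths = np.searchsorted(te, ev_times, side="right") - np.searchsorted(te, ev_times, side="left")
    surv = np.cumprod(1.0 - deaths / at_risk)
    if len(ev_times) == 0:
        return StepFunction(np.empty(0), np.empty(0), initial=1.0)
    return StepFunction(ev_times, surv, initial=1.0)


def km_survival_at(time, event, horizon: float) -> float:
    """Kaplan-Meier S(horizon); 1.0 when no events occur by then."""
    sf = kaplan_meier(time, event)
    if len(sf.x) == 0:
        return 1.0
    v = sf(horizon)
    return float(v) if np.ndim(v) == 0 else float(v)


def _censoring_survival(time, event) -> StepFunction:
    """Kaplan-Meier of the censoring distribution (event indicator flipped)."""
    return kaplan_meier(time, ~np.asarray(event).astype(bool))


# Discrimination -------------------------------------------------------------


def _truncate(time, event, horizon):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    t = np.minimum(time, horizon)
    e = event & (time <= horizon)
    return t, e


def c_index(predicted_risk, time, event, horizon: float) -> float:
    """Truncated Harrell concordance index.

    Outcomes are administratively censored at ``horizon``; a pair is
    evaluable iff the smaller observed time is an event time (at equal
    times, an event vs a censored observation is evaluable); the pair is
    concordant when the earlier-failing subject has the higher predicted
    risk, with risk ties counting 1/2.  Raises
    :class:`UndefinedMetricError` with zero evaluable pairs.
    """
    risk = np.asarray(predicted_risk, dtype=float)
    t, e = _truncate(time, event, horizon)
    order = np.argsort(t, kind="mergesort")
    t, e, risk = t[order], e[order], risk[order]
    n = len(t)
    concordant = 0.0
    evaluable = 0
    # chunked O(n^2) pair comparison
    chunk = max(1, int(2_000_000 // max(n, 1)))
    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        ti, ei, ri = t[sl, None], e[sl, None], risk[sl, None]
        # pair (i in chunk, j all): evaluable if e_i and (t_i < t_j or (t_i == t_j and not e_j))
        earlier = ti < t[None, :]
        same = ti == t[None, :]
        ev = ei & (earlier | (same & ~e[None, :]))
        evaluable += int(ev.sum())
        conc = np.where(ri > risk[None, :], 1.0, np.where(ri == risk[None, :], 0.5, 0.0))
        concordant += float((conc * ev).sum())
    if evaluable == 0:
        raise UndefinedMetricError("no evaluable pairs for the C-index at this horizon")
    return concordant / evaluable


# Prediction error -----------------------------------------------------------


def brier_score(
    predicted_survival,
    time,
    event,
    horizon: float,
    censoring_sf: Optional[StepFunction] = None,
) -> float:
    """IPCW Brier score at ``horizon``.

    Subjects dead by the horizon are weighted by 1/G(t-), survivors past
    the horizon by 1/G(horizon), and subjects censored before the horizon
    receive weight 0, where G is the Kaplan-Meier estimate of the
    censoring survival function (estimated on these records unless
    supplied).
    """
    p = np.asarray(predicted_survival, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if censoring_sf is None:
        censoring_sf = _censoring_survival(time, event)
    dead = event & (time <= horizon)
    alive = time > horizon
    g_dead = censoring_sf.left_limit(time) if len(censoring_sf.x) else np.ones(len(time))
    g_h = censoring_sf(horizon) if len(censoring_sf.x) else 1.0
    w = np.zeros(len(time))
    if np.any(dead):
        gd = np.atleast_1d(g_dead)[dead] if np.ndim(g_dead) else np.full(dead.sum(), g_dead)
        if np.any(gd <= 0):
            raise ValueError("censoring survival is 0 at a death time; reduce the horizon")
        w[dead] = 1.0 / gd
    if np.any(alive):
        if g_h <= 0:
            raise ValueError("censoring survival is 0 at the horizon; reduce the horizon")
        w[alive] = 1.0 / float(g_h)
    indicator = (~dead).astype(float)  # 1 if known alive at horizon (weight 0 if censored)
    return float(np.sum(w * (indicator - p) ** 2) / np.sum(w)) if w.sum() > 0 else np.nan


def percent_reduction(brier_model: float, brier_reference: float) -> float:
    """100 * (1 - model / reference); negative when the model is worse."""
    if brier_reference <= 0:
        raise ValueError("reference Brier score must be > 0")
    return 100.0 * (1.0 - brier_model / brier_reference)


# Splits ---------------------------------------------------------------------


def split_stacked(
    stacked: StackedDataset,
    fraction: float = 0.8,
    seed: int = 0,
    unit: str = "patient",
) -> Tuple[StackedDataset, StackedDataset]:
    """Random training/holdout split of the stacked data.

    With ``unit='patient'`` (default) every record of a patient goes to the
    same side, so no individual contributes to both model fitting and
    holdout evaluation; because patient counts per landmark age are large,
    the per-landmark record shares remain close to ``fraction``
    (stratification in expectation).  ``unit='record'`` samples records
    within each landmark-age stratum exactly.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rec = stacked.records
    rng = np.random.default_rng(seed)
    if unit == "patient":
        pats = pd.unique(rec["patient_id"])
        n_train = int(round(fraction * len(pats)))
        perm = rng.permutation(len(pats))
        train_pats = set(pats[perm[:n_train]])
        mask = rec["patient_id"].isin(train_pats).to_numpy()
    elif unit == "record":
        mask = np.zeros(len(rec), dtype=bool)
        for L in pd.unique(rec["L"]):
            idx = np.flatnonzero((rec["L"] == L).to_numpy())
            if len(idx) < 2:
                warnings.warn(f"landmark stratum {L} too small to split; all records to training")
                mask[idx] = True
                continue
            n_train = int(round(fraction * len(idx)))
            perm = rng.permutation(len(idx))
            mask[idx[perm[:n_train]]] = True
    else:
        raise ValueError("unit must be 'patient' or 'record'")
    train = StackedDataset(rec[mask].reset_index(drop=True), stacked.landmark_grid)
    hold = StackedDataset(rec[~mask].reset_index(drop=True), stacked.landmark_grid)
    return train, hold


# Scoring --------------------------------------------------------------------


def evaluate_predictions(
    records: pd.DataFrame,
    predictions: Dict[float, np.ndarray],
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    reference_predictions: Optional[Dict[float, np.ndarray]] = None,
) -> PerformanceReport:
    """Score predicted survival probabilities against observed outcomes.

    ``predictions[h]`` gives S(h) per record.  Risk ordering for the
    C-index is 1 - S(h).  IPCW censoring distributions are estimated per
    landmark age; pooled ("overall") metrics use the union of all records
    with their per-landmark censoring weights.  When
    ``reference_predictions`` (e.g. per-landmark Kaplan-Meier) is given,
    Brier percentage reductions are reported against it.
    """
    horizons = list(horizons)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy()
    Ls = records["L"].to_numpy() if "L" in records.columns else np.zeros(len(records))
    unique_L = pd.unique(Ls)

    cens = {}
    for L in unique_L:
        idx = np.flatnonzero(Ls == L)
        cens[L] = _censoring_survival(time[idx], event[idx])

    rows = []
    for L in sorted(unique_L):
        idx = np.flatnonzero(Ls == L)
        row = {"L": L, "n": len(idx), "n_events": int(np.sum((event[idx] != 0)))}
        for h in horizons:
            p = predictions[h][idx]
            try:
                row[f"c_index_{_hlab(h)}"] = c_index(1 - p, time[idx], event[idx], h)
            except UndefinedMetricError:
                row[f"c_index_{_hlab(h)}"] = np.nan
            try:
                row[f"brier_{_hlab(h)}"] = brier_score(p, time[idx], event[idx], h, cens[L])
            except ValueError:
                row[f"brier_{_hlab(h)}"] = np.nan
        rows.append(row)
    per_landmark = pd.DataFrame(rows)

    overall = {}
    reductions = {}
    for h in horizons:
        p = predictions[h]
        overall[f"c_index_{_hlab(h)}"] = c_index(1 - p, time, event, h)
        num = 0.0
        den = 0.0
        ref_num = 0.0
        for L in unique_L:
            idx = np.flatnonzero(Ls == L)
            wsum, sq = _ipcw_terms(p[idx], time[idx], event[idx], h, cens[L])
            num += sq
            den += wsum
            if reference_predictions is not None:
                _, ref_sq = _ipcw_terms(reference_predictions[h][idx], time[idx], event[idx], h, cens[L])
                ref_num += ref_sq
        overall[f"brier_{_hlab(h)}"] = num / den if den > 0 else np.nan
        if reference_predictions is not None and ref_num > 0:
            reductions[h] = percent_reduction(num / den, ref_num / den)
    return PerformanceReport(
        per_landmark=per_landmark,
        overall=overall,
        percent_reduction=reductions,
        n_records=len(records),
    )


def _hlab(h: float) -> str:
    return f"{int(h)}yr" if float(h).is_integer() else f"{h}yr"


def _ipcw_terms(p, time, event, horizon, censoring_sf):
    """(sum of weights, weighted squared error sum) for pooled Brier scores."""
    p = np.asarray(p, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    dead = event & (time <= horizon)
    alive = time > horizon
    w = np.zeros(len(time))
    if len(censoring_sf.x):
        g_dead = np.atleast_1d(censoring_sf.left_limit(time))
        g_h = float(censoring_sf(horizon))
    else:
        g_dead = np.ones(len(time))
        g_h = 1.0
    if np.any(dead):
        gd = g_dead[dead]
        if np.any(gd <= 0):
            raise ValueError("censoring survival is 0 at a death time")
        w[dead] = 1.0 / gd
    if np.any(alive):
        if g_h <= 0:
            raise ValueError("censoring survival is 0 at the horizon")
        w[alive] = 1.0 / g_h
    indicator = (~dead).astype(float)
    return float(w.sum()), float(np.sum(w * (indicator - p) ** 2))


def km_reference_predictions(
    records: pd.DataFrame, horizons: Sequence[float] = DEFAULT_HORIZONS
) -> Dict[float, np.ndarray]:
    """Per-landmark Kaplan-Meier S(h) applied to every record of that landmark."""
    Ls = records["L"].to_numpy() if "L" in records.columns else np.zeros(len(records))
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy()
    out = {h: np.empty(len(records)) for h in horizons}
    for L in pd.unique(Ls):
        idx = np.flatnonzero(Ls == L)
        for h in horizons:
            out[h][idx] = km_survival_at(time[idx], event[idx], h)
    return out


def evaluate_fit(
    fit: CoxFit,
    records: pd.DataFrame,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    include_km_reference: bool = True,
) -> PerformanceReport:
    """Predict with a fitted model on ``records`` and score it."""
    predictions = {h: predict_survival_at(fit, records, h) for h in horizons}
    ref = km_reference_predictions(records, horizons) if include_km_reference else None
    return evaluate_predictions(records, predictions, horizons, reference_predictions=ref)


# Monte-Carlo cross-validation ----------------------------------------------


def monte_carlo_cv(
    training: StackedDataset,
    fit_fn: Callable[[StackedDataset], CoxFit],
    n_reps: int = 50,
    inner_fraction: float = 0.8,
    seed: int = 0,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> PerformanceReport:
    """Repeated random inner splits: fit on the inner-training part, score
    on the inner-validation part, and summarize the metric distribution.

    ``fit_fn`` maps a stacked dataset to a fitted model (so any variant,
    including its feature engineering, can be cross-validated).  Failed
    repetitions are recorded and skipped; more than 50% failures is an
    error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    failures = 0
    for rep in range(n_reps):
        inner_seed = int(rng.integers(0, 2**31 - 1))
        inner_train, inner_val = split_stacked(training, inner_fraction, seed=inner_seed)
        if len(inner_val) == 0:
            raise ValueError("inner validation set is empty; lower inner_fraction")
        try:
            fit = fit_fn(inner_train)
            rep_report = evaluate_fit(fit, inner_val.records, horizons)
        except Exception as err:  # noqa: BLE001 - any failed repetition is recorded
            warnings.warn(f"cross-validation repetition {rep} failed: {err}")
            failures += 1
            continue
        results.append(rep_report.overall)
    if failures > n_reps / 2:
        raise RuntimeError(f"{failures}/{n_reps} cross-validation repetitions failed")
    if not results:
        raise RuntimeError("all cross-validation repetitions failed")
    frame = pd.DataFrame(results)
    cv_summary = pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1 if len(frame) > 1 else 0)})
    report = PerformanceReport(
        per_landmark=pd.DataFrame(),
        overall=frame.mean().to_dict(),
        percent_reduction={},
        cv_summary=cv_summary,
        n_records=len(training),
        n_failures=failures,
    )
    return report


# Calibration ----------------------------------------------------------------


def calibration_table(
    predictions: np.ndarray,
    time,
    event,
    horizon: float,
    n_groups: int = 10,
    L: Optional[float] = None,
) -> CalibrationTable:
    """Decile calibration: mean predicted vs Kaplan-Meier observed survival.

    Groups are quantile bins of the predicted survival probability (ties
    may merge bins); the observed column is the Kaplan-Meier estimate at
    the horizon within each group with a Greenwood standard error.
    """
    p = np.asarray(predictions, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_groups + 1)))
    if len(edges) < 2:
        groups = np.zeros(len(p), dtype=int)
        n_eff = 1
    else:
        groups = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
        n_eff = len(edges) - 1
    rows = []
    for g in range(n_eff):
        idx = np.flatnonzero(groups == g)
        if len(idx) == 0:
            continue
        obs, se = _km_with_se(time[idx], event[idx], horizon)
        rows.append(
            {
                "group": g,
                "n": len(idx),
                "mean_predicted": float(p[idx].mean()),
                "observed": obs,
                "observed_se": se,
                "lower_edge": edges[g] if len(edges) >= 2 else float(p.min()),
                "upper_edge": edges[g + 1] if len(edges) >= 2 else float(p.max()),
            }
        )
    return CalibrationTable(horizon=horizon, table=pd.DataFrame(rows), L=L)


def _km_with_se(time, event, horizon) -> Tuple[float, float]:
    """Kaplan-Meier survival at horizon with the Greenwood standard error."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    te = np.sort(t[e & (t <= horizon)])
    ev_times = np.unique(te)
    if len(ev_times) == 0:
        return 1.0, 0.0
    n = len(t)
    at_risk = n - np.searchsorted(t, ev_times, side="left")
    deaths = np.searchsorted(te, ev_times, side="right") - np.searchsorted(te, ev_times, side="left")
    s = float(np.prod(1.0 - deaths / at_risk))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.sum(deaths / (at_risk * (at_risk - deaths)))
    se = s * np.sqrt(gw) if np.isfinite(gw) else np.nan
    return s, float(se)
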