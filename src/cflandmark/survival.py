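"""Cox proportional-hazards engine for landmark supermodels.

Implements the stratified Cox partial likelihood with:

* Newton-Raphson maximization with step-halving (Breslow ties by default,
  Efron optional);
* terms whose log-hazard-ratio varies deterministically with time since
  landmark (interaction with a basis function of time evaluated at event
  times inside the partial likelihood — the landmarking device for
  time-varying coefficients);
* robust (cluster sandwich) covariance, clustering on the patient
  identifier so that the same individual appearing in several landmark
  datasets is handled correctly;
* per-stratum Breslow baseline cumulative hazards, giving the full
  specification of the dynamic prediction model;
* survival-curve prediction S(t | landmark age, covariates) on [0, w].

Covariates are centered at the dataset means before fitting; baselines
refer to the centered reference and the centering vector is serialized
with the fit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "TimeBasis",
    "TermSpec",
    "CoxModelSpec",
    "StepFunction",
    "SurvivalCurve",
    "CoxFit",
    "ConvergenceError",
    "RankDeficiencyError",
    "fit_cox",
    "breslow_baseline",
    "predict_survival",
    "predict_survival_at",
    "fit_to_json",
    "fit_from_json",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: Optional[List[float]] = None):
        super().__init__(message)
        self.trace = trace or []


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class TimeBasis:
    """Deterministic basis function of time-since-landmark.

    kind 'linear': f(t) = t / scale.  kind 'bspline': the ``index``-th cubic
    B-spline basis function on internal knots over [0, scale].
    """

    kind: str = "linear"
    scale: float = 10.0
    index: int = 0
    n_basis: int = 3

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "linear":
            return t / self.scale
        if self.kind == "bspline":
            from scipy.interpolate import BSpline

            degree = 3
            n_inner = max(self.n_basis - degree + 1, 0)
            inner = np.linspace(0, self.scale, n_inner + 2)[1:-1]
            knots = np.concatenate([[0.0] * (degree + 1), inner, [self.scale] * (degree + 1)])
            n_funcs = len(knots) - degree - 1
            coef = np.zeros(n_funcs)
            coef[min(self.index, n_funcs - 1)] = 1.0
            return BSpline(knots, coef, degree, extrapolate=False)(np.clip(t, 0, self.scale))
        raise ValueError(f"unknown time basis kind '{self.kind}'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TermSpec:
    """One model term: a data column, optionally interacted with a time basis."""

    name: str
    column: str
    time_basis: Optional[TimeBasis] = None


@dataclass(frozen=True)
class CoxModelSpec:
    """Declarative Cox model: terms, stratification, clustering, ties method."""

    terms: Tuple[TermSpec, ...]
    strata: Optional[str] = None
    cluster: Optional[str] = "patient_id"
    ties: str = "breslow"

    def __post_init__(self):
        if self.ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")

    @property
    def names(self) -> List[str]:
        return [t.name for t in self.terms]

    @property
    def has_time_varying(self) -> bool:
        return any(t.time_basis is not None for t in self.terms)


@dataclass
class StepFunction:
    """Right-continuous step function.

    Before the first breakpoint the value is ``initial`` — 0 for cumulative
    hazards, 1 for survival functions.
    """

    x: np.ndarray
    y: np.ndarray
    initial: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("breakpoints and values must have equal length")
        if len(self.x) > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("breakpoints must be strictly increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t, side="right") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.initial)
        return out if out.ndim else float(out)

    def left_limit(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t, side="left") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.initial)
        return out if out.ndim else float(out)


@dataclass
class SurvivalCurve:
    """Predicted survival probabilities on a time grid in [0, w]."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.survival[idx]


@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, covariances and baseline hazards."""

    spec: CoxModelSpec
    names: List[str]
    beta: np.ndarray
    naive_covariance: np.ndarray
    robust_covariance: np.ndarray
    baseline_cumhaz: Dict[object, StepFunction]
    centering: np.ndarray
    loglik: float
    loglik_null: float
    n_events: int
    n_records: int
    n_clusters: int
    converged: bool
    n_iter: int
    variant: Optional[str] = None

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_covariance))

    @property
    def naive_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.naive_covariance))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "hazard_ratio": np.exp(self.beta),
                "se_naive": self.naive_se,
                "se_robust": self.robust_se,
            },
            index=self.names,
        )


# ---------------------------------------------------------------------------


def _as_records(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    if hasattr(data, "records"):
        return data.records
    raise TypeError(f"cannot extract records from {type(data)!r}")


def _design(df: pd.DataFrame, spec: CoxModelSpec, centering: Optional[np.ndarray] = None):
    cols = []
    for t in spec.terms:
        if t.column not in df.columns:
            raise KeyError(f"term '{t.name}' references missing column '{t.column}'")
        cols.append(df[t.column].to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    if centering is None:
        centering = X.mean(axis=0) if len(df) else np.zeros(X.shape[1])
    return X - centering, centering


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] == 0:
        return
    _, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (d.max() if d.size else 0.0)
    bad = [names[i] for i in range(len(names)) if d[i] <= tol]
    if bad:
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear terms: {bad}")


@dataclass
class _Stratum:
    key: object
    times: np.ndarray   # ascending
    events: np.ndarray  # bool
    X: np.ndarray       # centered, sorted like times
    order: np.ndarray   # positions into the original record array
    ev_times: np.ndarray      # distinct event times
    ev_start: np.ndarray      # first risk-set index per distinct event time
    ev_counts: np.ndarray     # number of deaths per distinct event time


def _split_strata(df: pd.DataFrame, spec: CoxModelSpec, X: np.ndarray) -> List[_Stratum]:
    times_all = df["time"].to_numpy(dtype=float)
    events_all = df["event"].to_numpy() != 0
    if np.any(times_all <= 0):
        raise ValueError("all survival times must be > 0")
    if spec.strata is None:
        groups = {None: np.arange(len(df))}
    else:
        keys = df[spec.strata].to_numpy()
        groups = {}
        for k in pd.unique(keys):
            groups[k] = np.flatnonzero(keys == k)
    strata = []
    for key, idx in groups.items():
        t = times_all[idx]
        order = np.argsort(t, kind="mergesort")
        idx = idx[order]
        t = t[order]
        e = events_all[idx]
        te = t[e]
        ev_times = np.unique(te)
        ev_start = np.searchsorted(t, ev_times, side="left")
        ev_counts = np.searchsorted(te, ev_times, side="right") - np.searchsorted(te, ev_times, side="left")
        if len(ev_times) == 0:
            warnings.warn(f"stratum {key!r} has no events; its baseline hazard is flat")
        strata.append(_Stratum(key, t, e, X[idx], idx, ev_times, ev_start, ev_counts))
    return strata


def _basis_matrix(spec: CoxModelSpec, t: float, p: int) -> np.ndarray:
    f = np.ones(p)
    for j, term in enumerate(spec.terms):
        if term.time_basis is not None:
            f[j] = float(term.time_basis.evaluate(t))
    return f


def _stratum_quantities_fast(s: _Stratum, beta: np.ndarray, want_info: bool = True):
    """Breslow, time-constant terms: log-likelihood, score, information.

    Fully vectorized over the distinct event times via suffix cumulative
    sums of exp(eta), exp(eta)*X and exp(eta)*X X'."""
    X, t, e = s.X, s.times, s.events
    n, p = X.shape
    eta = X @ beta
    m = eta.max() if n else 0.0
    w = np.exp(eta - m)
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    if len(s.ev_times) == 0:
        return ll, score, info
    S0 = np.cumsum(w[::-1])[::-1]
    d = s.ev_counts.astype(float)
    start = s.ev_start
    S0k = S0[start]
    ll = float(eta[e].sum()) - float(d @ (np.log(S0k) + m))
    if p:
        S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        meank = S1[start] / S0k[:, None]
        score = X[e].sum(axis=0) - d @ meank
        if want_info:
            XX = np.einsum("ni,nj->nij", X, X)
            S2 = np.cumsum((w[:, None, None] * XX)[::-1], axis=0)[::-1]
            info = np.einsum("k,kij->ij", d / S0k, S2[start]) - np.einsum("k,ki,kj->ij", d, meank, meank)
    return ll, score, info


def _stratum_quantities_general(s: _Stratum, beta: np.ndarray, spec: CoxModelSpec, want_info: bool = True):
    """Event-time loop: handles time-varying terms and Efron ties."""
    X, t, e = s.X, s.times, s.events
    n, p = X.shape
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    efron = spec.ties == "efron"
    for k in range(len(s.ev_times)):
        tt, start, d = s.ev_times[k], s.ev_start[k], s.ev_counts[k]
        f = _basis_matrix(spec, tt, p)
        Z = X[start:] * f  # risk set covariates at this event time
        eta = Z @ beta
        m = eta.max()
        w = np.exp(eta - m)
        S0 = w.sum()
        S1 = w @ Z
        tie_mask = e[start:] & (t[start:] == tt)
        Zt = Z[tie_mask]
        ll += float((Zt @ beta).sum())
        if efron and d > 1:
            wt = w[tie_mask]
            S0t = wt.sum()
            S1t = wt @ Zt
            if want_info and p:
                S2 = Z.T @ (w[:, None] * Z)
                S2t = Zt.T @ (wt[:, None] * Zt)
            for j in range(d):
                S0j = S0 - (j / d) * S0t
                S1j = S1 - (j / d) * S1t
                ll -= np.log(S0j) + m
                if p:
                    mean = S1j / S0j
                    score -= mean
                    if want_info:
                        S2j = S2 - (j / d) * S2t
                        info += S2j / S0j - np.outer(mean, mean)
            if p:
                score += Zt.sum(axis=0)
        else:
            ll -= d * (np.log(S0) + m)
            if p:
                mean = S1 / S0
                score += Zt.sum(axis=0) - d * mean
                if want_info:
                    S2 = Z.T @ (w[:, None] * Z)
                    info += d * (S2 / S0 - np.outer(mean, mean))
    return ll, score, info


def _loglik_score_info(strata: List[_Stratum], beta: np.ndarray, spec: CoxModelSpec, want_info=True):
    fast = spec.ties == "breslow" and not spec.has_time_varying
    p = len(beta)
    ll, score, info = 0.0, np.zeros(p), np.zeros((p, p))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for s in strata:
            if fast:
                l, sc, inf = _stratum_quantities_fast(s, beta, want_info)
            else:
                l, sc, inf = _stratum_quantities_general(s, beta, spec, want_info)
            ll += l
            score += sc
            info += inf
    return ll, score, info


def _score_residuals_fast(s: _Stratum, beta: np.ndarray) -> np.ndarray:
    """Breslow/time-constant score residuals via cumulative sums, O(n p)."""
    X, t, e = s.X, s.times, s.events
    n, p = X.shape
    eta = X @ beta
    m = eta.max() if n else 0.0
    w = np.exp(eta - m)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    K = len(s.ev_times)
    if K == 0:
        return np.zeros((n, p))
    S0k = S0[s.ev_start]
    S1k = S1[s.ev_start]
    d = s.ev_counts.astype(float)
    A_cum = np.concatenate([[0.0], np.cumsum(d / S0k)])
    B_cum = np.concatenate([np.zeros((1, p)), np.cumsum((d / S0k**2)[:, None] * S1k, axis=0)])
    idx = np.searchsorted(s.ev_times, t, side="right")  # event times <= T_i
    U = -w[:, None] * (X * A_cum[idx][:, None] - B_cum[idx])
    own = np.searchsorted(s.ev_times, t[e], side="left")
    U[e] += X[e] - S1k[own] / S0k[own][:, None]
    return U


def _score_residuals(strata: List[_Stratum], beta: np.ndarray, spec: CoxModelSpec, n_records: int) -> np.ndarray:
    """Per-record score residuals (for the cluster sandwich)."""
    p = len(beta)
    U = np.zeros((n_records, p))
    efron = spec.ties == "efron"
    fast = spec.ties == "breslow" and not spec.has_time_varying
    if fast:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for s in strata:
                if p:
                    U[s.order] = _score_residuals_fast(s, beta)
        return U
    for s in strata:
        X, t, e = s.X, s.times, s.events
        n = len(t)
        if p == 0 or len(s.ev_times) == 0:
            continue
        Us = np.zeros((n, p))
        for k in range(len(s.ev_times)):
            tt, start, d = s.ev_times[k], s.ev_start[k], s.ev_counts[k]
            f = _basis_matrix(spec, tt, p)
            Z = X[start:] * f
            eta = Z @ beta
            m = eta.max()
            w = np.exp(eta - m)
            S0 = w.sum()
            S1 = w @ Z
            tie_mask = e[start:] & (t[start:] == tt)
            if efron and d > 1:
                wt = w[tie_mask]
                S0t = wt.sum()
                S1t = wt @ Z[tie_mask]
                means = []
                for j in range(d):
                    S0j = S0 - (j / d) * S0t
                    S1j = S1 - (j / d) * S1t
                    mean_j = S1j / S0j
                    means.append(mean_j)
                    wj = w.copy()
                    wj[tie_mask] *= 1 - j / d
                    Us[start:] -= (wj / S0j)[:, None] * (Z - mean_j)
                mbar = np.mean(means, axis=0)
                Us[start:][tie_mask] += Z[tie_mask] - mbar
            else:
                mean = S1 / S0
                Us[start:] -= (d * w / S0)[:, None] * (Z - mean)
                Us[start:][tie_mask] += Z[tie_mask] - mean
        U[s.order] = Us
    return U


def fit_cox(
    data,
    spec: CoxModelSpec,
    center: bool = True,
    score_tol: float = 1e-9,
    max_iter: int = 50,
    variant: Optional[str] = None,
) -> CoxFit:
    """Maximize the stratified Cox partial likelihood.

    Convergence requires the score max-norm to fall below
    ``score_tol * max(1, n_events)`` (the score scales with the number of
    events).  Raises :class:`ConvergenceError` after ``max_iter``
    Newton-Raphson iterations with step-halving, and
    :class:`RankDeficiencyError` for a singular design.
    """
    df = _as_records(data)
    if len(df) == 0:
        raise ValueError("cannot fit a Cox model to an empty dataset")
    X, centering = _design(df, spec, None if center else np.zeros(len(spec.terms)))
    # rank check on the effective design: time-varying columns evaluated at
    # each record's own time, so x and x*f(t) are not flagged as collinear
    if spec.has_time_varying:
        Xeff = X.copy()
        t_rec = df["time"].to_numpy(dtype=float)
        for j, term in enumerate(spec.terms):
            if term.time_basis is not None:
                Xeff[:, j] = Xeff[:, j] * term.time_basis.evaluate(t_rec)
        _check_rank(Xeff, spec.names)
    else:
        _check_rank(X, spec.names)
    strata = _split_strata(df, spec, X)
    n_events = int(sum(s.events.sum() for s in strata))
    p = X.shape[1]

    beta = np.zeros(p)
    ll_null, _, _ = _loglik_score_info(strata, beta, spec, want_info=False)
    tol = score_tol * max(1.0, n_events)
    trace = []
    converged = p == 0
    ll = ll_null
    n_iter = 0
    if p:
        ll, score, info = _loglik_score_info(strata, beta, spec)
        for n_iter in range(1, max_iter + 1):
            trace.append(ll)
            if np.max(np.abs(score)) <= tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(f"singular information matrix at iteration {n_iter}", trace) from err
            new_beta = beta + step
            new_ll, new_score, new_info = _loglik_score_info(strata, new_beta, spec)
            halvings = 0
            while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
                halvings += 1
                if halvings > 30:
                    break
                step = step / 2
                new_beta = beta + step
                new_ll, new_score, new_info = _loglik_score_info(strata, new_beta, spec)
            if halvings > 30 and new_ll < ll:
                raise ConvergenceError("step-halving failed to improve the partial likelihood", trace)
            rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
            beta, ll, score, info = new_beta, new_ll, new_score, new_info
            if np.max(np.abs(score)) <= tol or rel_change < 1e-13:
                converged = np.max(np.abs(score)) <= max(tol, 1e-6 * max(1.0, n_events))
                break
        else:
            raise ConvergenceError(
                f"no convergence after {max_iter} iterations (max |score| = {np.max(np.abs(score)):.3e})",
                trace,
            )
        if not converged:
            raise ConvergenceError(
                f"stalled with max |score| = {np.max(np.abs(score)):.3e} above tolerance {tol:.3e}", trace
            )
    # covariances
    if p:
        _, _, info = _loglik_score_info(strata, beta, spec)
        naive = np.linalg.inv(info)
        U = _score_residuals(strata, beta, spec, len(df))
        if spec.cluster is not None and spec.cluster in df.columns:
            cl = df[spec.cluster].to_numpy()
            codes, _ = pd.factorize(cl)
            n_clusters = int(codes.max()) + 1
            G = np.zeros((n_clusters, p))
            np.add.at(G, codes, U)
        else:
            G = U
            n_clusters = len(df)
        robust = naive @ (G.T @ G) @ naive
    else:
        naive = np.zeros((0, 0))
        robust = np.zeros((0, 0))
        n_clusters = len(df)

    baselines = {s.key: _breslow_from_stratum(s, beta, spec) for s in strata}

    return CoxFit(
        spec=spec,
        names=spec.names,
        beta=beta,
        naive_covariance=naive,
        robust_covariance=robust,
        baseline_cumhaz=baselines,
        centering=centering,
        loglik=ll,
        loglik_null=ll_null,
        n_events=n_events,
        n_records=len(df),
        n_clusters=n_clusters,
        converged=converged,
        n_iter=n_iter,
        variant=variant,
    )


def _breslow_from_stratum(s: _Stratum, beta: np.ndarray, spec: CoxModelSpec) -> StepFunction:
    p = len(beta)
    if len(s.ev_times) == 0:
        return StepFunction(np.empty(0), np.empty(0))
    efron = spec.ties == "efron"
    if not efron and not spec.has_time_varying:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            eta = s.X @ beta if p else np.zeros(len(s.times))
            m = eta.max() if len(eta) else 0.0
            w = np.exp(eta - m)
            S0 = np.cumsum(w[::-1])[::-1]
            incs = s.ev_counts / (S0[s.ev_start] * np.exp(m))
        return StepFunction(s.ev_times, np.cumsum(incs))
    incs = np.empty(len(s.ev_times))
    for k in range(len(s.ev_times)):
        tt, start, d = s.ev_times[k], s.ev_start[k], s.ev_counts[k]
        if p:
            f = _basis_matrix(spec, tt, p)
            Z = s.X[start:] * f
            w = np.exp(Z @ beta)
        else:
            w = np.ones(len(s.times) - start)
        S0 = w.sum()
        if efron and d > 1:
            tie_mask = s.events[start:] & (s.times[start:] == tt)
            S0t = w[tie_mask].sum()
            incs[k] = sum(1.0 / (S0 - (j / d) * S0t) for j in range(d))
        else:
            incs[k] = d / S0
    return StepFunction(s.ev_times, np.cumsum(incs))


def breslow_baseline(data, spec: CoxModelSpec, beta: np.ndarray, centering: Optional[np.ndarray] = None,
                     stratum: object = "__all__") -> Union[StepFunction, Dict[object, StepFunction]]:
    """Breslow cumulative baseline hazard(s) at a given coefficient vector.

    Each increment is (deaths at t) / sum over the risk set of
    exp(linear predictor at t).  Returns a single step function when
    ``stratum`` is given, else a map stratum -> step function.
    """
    df = _as_records(data)
    beta = np.asarray(beta, dtype=float)
    X, centering = _design(df, spec, centering)
    strata = _split_strata(df, spec, X)
    out = {s.key: _breslow_from_stratum(s, beta, spec) for s in strata}
    if stratum != "__all__":
        if stratum not in out:
            raise KeyError(f"stratum {stratum!r} not present; available: {sorted(map(repr, out))}")
        return out[stratum]
    if spec.strata is None:
        return out[None]
    return out


def _resolve_stratum(fit: CoxFit, L) -> object:
    if fit.spec.strata is None:
        return None
    keys = list(fit.baseline_cumhaz)
    for k in keys:
        if k == L:
            return k
        try:
            if float(k) == float(L):
                return k
        except (TypeError, ValueError):
            continue
    hint = ""
    try:
        numeric = [(abs(float(k) - float(L)), k) for k in keys]
        hint = f"; nearest fitted stratum is {min(numeric)[1]!r}"
    except (TypeError, ValueError):
        pass
    raise KeyError(f"landmark age {L!r} has no fitted stratum{hint}")


def _linear_predictor(fit: CoxFit, covariates) -> np.ndarray:
    x = np.array([float(covariates[t.column]) for t in fit.spec.terms])
    return x - fit.centering


def predict_survival(fit: CoxFit, covariates, L=None, times: Optional[np.ndarray] = None) -> SurvivalCurve:
    """Predicted survival curve S(t | L, covariates) on a step grid.

    For a stratified supermodel, ``L`` selects the baseline stratum (no
    extrapolation outside the fitted landmark grid).  With time-varying
    coefficient terms the cumulative hazard is accumulated over baseline
    jumps with the time basis evaluated at each jump.
    """
    key = _resolve_stratum(fit, L)
    H0 = fit.baseline_cumhaz[key]
    xc = _linear_predictor(fit, covariates)
    if times is None:
        times = np.concatenate([[0.0], H0.x]) if len(H0.x) else np.array([0.0])
    times = np.asarray(times, dtype=float)
    if fit.spec.has_time_varying:
        jumps = H0.x
        dH = np.diff(np.concatenate([[0.0], H0.y]))
        p = len(fit.beta)
        F = np.ones((len(jumps), p))
        for j, term in enumerate(fit.spec.terms):
            if term.time_basis is not None:
                F[:, j] = term.time_basis.evaluate(jumps)
        lp_at_jumps = np.clip(F @ (fit.beta * xc), -700.0, 700.0)
        cumH = np.cumsum(dH * np.exp(lp_at_jumps))
        idx = np.searchsorted(jumps, times, side="right") - 1
        H = np.where(idx >= 0, np.concatenate([[0.0], cumH])[idx + 1], 0.0)
    else:
        H = np.asarray(H0(times)) * np.exp(np.clip(float(xc @ fit.beta), -700.0, 700.0))
    S = np.exp(-H)
    return SurvivalCurve(times=times, survival=S)


def predict_survival_at(fit: CoxFit, df: pd.DataFrame, horizon: float) -> np.ndarray:
    """Vectorized S(horizon | L, covariates) for every record of ``df``."""
    X, _ = _design(df, fit.spec, fit.centering)
    out = np.empty(len(df))
    if fit.spec.strata is not None:
        keys = df[fit.spec.strata].to_numpy()
        groups = {k: np.flatnonzero(keys == k) for k in pd.unique(keys)}
    else:
        groups = {None: np.arange(len(df))}
    for key, idx in groups.items():
        skey = _resolve_stratum(fit, key) if fit.spec.strata is not None else None
        H0 = fit.baseline_cumhaz[skey]
        if fit.spec.has_time_varying:
            jumps_mask = H0.x <= horizon
            jumps = H0.x[jumps_mask]
            dH = np.diff(np.concatenate([[0.0], H0.y]))[jumps_mask]
            p = len(fit.beta)
            F = np.ones((len(jumps), p))
            for j, term in enumerate(fit.spec.terms):
                if term.time_basis is not None:
                    F[:, j] = term.time_basis.evaluate(jumps)
            # H_i = sum_k dH_k exp(sum_j beta_j f_j(t_k) x_ij)
            lp = np.clip((X[idx] * fit.beta) @ F.T, -700.0, 700.0)  # (n_idx, n_jumps)
            H = (np.exp(lp) * dH).sum(axis=1)
        else:
            lp = np.clip(X[idx] @ fit.beta, -700.0, 700.0)
            h0 = float(H0(horizon))
            H = h0 * np.exp(lp) if h0 > 0 else np.zeros(len(idx))
        out[idx] = np.exp(-H)
    return out


# Serialization --------------------------------------------------------------


def fit_to_json(fit: CoxFit) -> str:
    doc = {
        "model": "cox-landmark-supermodel",
        "variant": fit.variant,
        "ties": fit.spec.ties,
        "strata": fit.spec.strata,
        "cluster": fit.spec.cluster,
        "terms": [
            {
                "name": t.name,
                "column": t.column,
                "time_basis": t.time_basis.to_dict() if t.time_basis else None,
            }
            for t in fit.spec.terms
        ],
        "centering": fit.centering.tolist(),
        "coefficients": dict(zip(fit.names, fit.beta.tolist())),
        "robust_se": dict(zip(fit.names, fit.robust_se.tolist())),
        "naive_covariance": fit.naive_covariance.tolist(),
        "robust_covariance": fit.robust_covariance.tolist(),
        "loglik": float(fit.loglik),
        "loglik_null": float(fit.loglik_null),
        "n_events": int(fit.n_events),
        "n_records": int(fit.n_records),
        "n_clusters": int(fit.n_clusters),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "baseline_cumhaz": {
            json.dumps(k) if not isinstance(k, str) else k: {
                "breakpoints": sf.x.tolist(),
                "values": sf.y.tolist(),
            }
            for k, sf in _jsonable_baselines(fit.baseline_cumhaz).items()
        },
    }
    return json.dumps(doc, indent=2)


def _jsonable_baselines(baselines: Dict[object, StepFunction]) -> Dict[object, StepFunction]:
    out = {}
    for k, v in baselines.items():
        if k is None:
            out["__none__"] = v
        elif isinstance(k, (np.integer, np.floating)):
            out[float(k)] = v
        else:
            out[k] = v
    return out


def fit_from_json(text: str) -> CoxFit:
    doc = json.loads(text)
    terms = tuple(
        TermSpec(
            name=t["name"],
            column=t["column"],
            time_basis=TimeBasis(**t["time_basis"]) if t.get("time_basis") else None,
        )
        for t in doc["terms"]
    )
    spec = CoxModelSpec(terms=terms, strata=doc["strata"], cluster=doc["cluster"], ties=doc["ties"])
    names = [t.name for t in terms]
    beta = np.array([doc["coefficients"][n] for n in names])
    baselines: Dict[object, StepFunction] = {}
    for k, v in doc["baseline_cumhaz"].items():
        if k == "__none__":
            key: object = None
        else:
            try:
                key = float(json.loads(k)) if not isinstance(k, (int, float)) else float(k)
            except (ValueError, json.JSONDecodeError):
                key = k
        baselines[key] = StepFunction(np.asarray(v["breakpoints"]), np.asarray(v["values"]))
    robust = np.asarray(doc["robust_covariance"])
    naive = np.asarray(doc["naive_covariance"])
    return CoxFit(
        spec=spec,
        names=names,
        beta=beta,
        naive_covariance=naive,
        robust_covariance=robust,
        baseline_cumhaz=baselines,
        centering=np.asarray(doc["centering"]),
        loglik=doc["loglik"],
        loglik_null=doc["loglik_null"],
        n_events=doc["n_events"],
        n_records=doc["n_records"],
        n_clusters=doc["n_clusters"],
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        variant=doc.get("variant"),
    )
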