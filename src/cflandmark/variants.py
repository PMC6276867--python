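"""The six dynamic-prediction model variants.

All variants are Cox models over the landmark/stacked datasets:

1. separate models fitted from each landmark age;
2. the basic supermodel — one model on the stacked data with a separate
   (stratified) baseline hazard per landmark age and common coefficients;
3. variant 2 plus interactions of every predictor with a polynomial basis
   in the scaled landmark age u = (L - 18) / (50 - 18), letting log hazard
   ratios vary smoothly with landmark age;
4. variant 2 plus predictor x time-since-landmark interactions (linear
   f(t) = t/w by default, B-spline optional), i.e. time-varying
   coefficients via the landmarking device; optionally restricted to
   FEV1%, the strongest predictor;
5. a common (unstratified) baseline hazard with the effect of landmark age
   entering the log hazard through the u, u^2 regression terms;
6. variant 2 plus mixed-model fitted values and slopes at the landmark age
   for FEV1%, FVC% and weight as additional predictors (alongside the
   last-observation-carried-forward values by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .landmark import DEFAULT_PREDICTORS, StackedDataset
from .survival import (
    ConvergenceError,
    CoxFit,
    CoxModelSpec,
    RankDeficiencyError,
    TermSpec,
    TimeBasis,
    fit_cox,
    predict_survival_at,
)

__all__ = [
    "VariantOptions",
    "build_variant",
    "add_derived_columns",
    "fit_variant",
    "SeparateLandmarkFits",
    "MIXED_FEATURE_COLUMNS",
    "LANDMARK_AGE_RANGE",
]

#: Landmark-age range used to scale the u basis: u = (L - 18) / 32.
LANDMARK_AGE_RANGE: Tuple[float, float] = (18.0, 50.0)

#: Columns appended by the two-stage (mixed-model) summaries.
MIXED_FEATURE_COLUMNS: Tuple[str, ...] = (
    "fev1_pct_fit",
    "fev1_pct_slope",
    "fvc_pct_fit",
    "fvc_pct_slope",
    "weight_fit",
    "weight_slope",
)


@dataclass(frozen=True)
class VariantOptions:
    """Configuration of one model variant.

    ``landmark_basis_degree`` controls the polynomial in u for variants 3
    and 5 (degree 2 -> terms u, u^2); ``time_basis`` is 'linear' or
    'bspline' for variant 4; ``fev1_only_time_varying`` restricts variant
    4's time-varying coefficients to FEV1%; ``include_locf_with_mixed``
    keeps the LOCF terms alongside the mixed-model summaries in variant 6.
    """

    variant: int
    horizon: float = 10.0
    landmark_basis_degree: int = 2
    time_basis: str = "linear"
    time_basis_df: int = 3
    fev1_only_time_varying: bool = False
    include_locf_with_mixed: bool = True
    ties: str = "breslow"
    cluster: Optional[str] = "patient_id"

    def __post_init__(self):
        if self.variant not in range(1, 7):
            raise ValueError("variant must be in 1..6")
        if self.landmark_basis_degree < 0:
            raise ValueError("landmark_basis_degree must be >= 0")
        if self.time_basis not in ("linear", "bspline"):
            raise ValueError("time_basis must be 'linear' or 'bspline'")


def _u_of_L(L):
    lo, hi = LANDMARK_AGE_RANGE
    return (np.asarray(L, dtype=float) - lo) / (hi - lo)


def add_derived_columns(
    df: pd.DataFrame,
    options: VariantOptions,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
) -> pd.DataFrame:
    """Append the derived columns a variant's terms reference.

    Adds u = (L-18)/32 powers and, for variant 3, the predictor x u^k
    interaction columns.  Idempotent; returns a copy.  Works both on
    datasets (many rows) and on single-row prediction profiles, so the same
    transformation is applied at fit and at prediction time.
    """
    out = df.copy()
    deg = options.landmark_basis_degree
    if options.variant in (3, 5):
        u = _u_of_L(out["L"])
        for k in range(1, deg + 1):
            out[f"u{k}"] = u**k
        if options.variant == 3:
            for p in predictors:
                for k in range(1, deg + 1):
                    out[f"{p}__u{k}"] = out[p] * out[f"u{k}"]
    return out


def _base_terms(predictors: Sequence[str]) -> List[TermSpec]:
    return [TermSpec(name=p, column=p) for p in predictors]


def build_variant(
    options: VariantOptions,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    landmark_grid: Optional[Sequence[float]] = None,
) -> Union[CoxModelSpec, Dict[float, CoxModelSpec]]:
    """Build the CoxModelSpec(s) for one variant.

    Variant 1 returns a map landmark age -> spec (one unstratified model
    per landmark dataset; ``landmark_grid`` required); all other variants
    return a single spec for the stacked dataset.
    """
    predictors = list(predictors)
    terms = _base_terms(predictors)
    v = options.variant

    if v == 1:
        if landmark_grid is None:
            raise ValueError("variant 1 requires a landmark_grid")
        spec = CoxModelSpec(terms=tuple(terms), strata=None, cluster=options.cluster, ties=options.ties)
        return {float(L): spec for L in landmark_grid}

    if v == 2:
        return CoxModelSpec(terms=tuple(terms), strata="L", cluster=options.cluster, ties=options.ties)

    if v == 3:
        for p in predictors:
            for k in range(1, options.landmark_basis_degree + 1):
                terms.append(TermSpec(name=f"{p}:u^{k}", column=f"{p}__u{k}"))
        return CoxModelSpec(terms=tuple(terms), strata="L", cluster=options.cluster, ties=options.ties)

    if v == 4:
        tv_predictors = ["fev1_pct"] if options.fev1_only_time_varying else predictors
        if options.time_basis == "linear":
            bases = [TimeBasis(kind="linear", scale=options.horizon)]
        else:
            bases = [
                TimeBasis(kind="bspline", scale=options.horizon, index=i, n_basis=options.time_basis_df)
                for i in range(options.time_basis_df)
            ]
        for p in tv_predictors:
            for i, b in enumerate(bases):
                suffix = "t" if options.time_basis == "linear" else f"t_b{i}"
                terms.append(TermSpec(name=f"{p}:{suffix}", column=p, time_basis=b))
        return CoxModelSpec(terms=tuple(terms), strata="L", cluster=options.cluster, ties=options.ties)

    if v == 5:
        for k in range(1, max(options.landmark_basis_degree, 1) + 1):
            terms.append(TermSpec(name=f"u^{k}", column=f"u{k}"))
        return CoxModelSpec(terms=tuple(terms), strata=None, cluster=options.cluster, ties=options.ties)

    # v == 6
    if not options.include_locf_with_mixed:
        keep = [t for t in terms if t.column not in ("fev1_pct", "fvc_pct", "weight")]
        terms = keep
    for c in MIXED_FEATURE_COLUMNS:
        terms.append(TermSpec(name=c, column=c))
    return CoxModelSpec(terms=tuple(terms), strata="L", cluster=options.cluster, ties=options.ties)


@dataclass
class SeparateLandmarkFits:
    """Variant 1: one independently fitted Cox model per landmark age.

    Landmark datasets too sparse to support the full predictor set (zero
    variance or collinear columns, or a non-convergent partial likelihood,
    as happens at the older landmark ages) fall back to the covariate-free
    model, i.e. the Nelson-Aalen baseline alone; ``fallback_L`` records
    which ages did.
    """

    fits: Dict[float, CoxFit]
    fallback_L: List[float] = field(default_factory=list)

    def predict_at(self, df: pd.DataFrame, horizon: float) -> np.ndarray:
        out = np.empty(len(df))
        Ls = df["L"].to_numpy(dtype=float)
        for L in np.unique(Ls):
            if L not in self.fits:
                raise KeyError(f"no fitted model for landmark age {L}")
            idx = np.flatnonzero(Ls == L)
            out[idx] = predict_survival_at(self.fits[L], df.iloc[idx], horizon)
        return out

    @property
    def loglik(self) -> float:
        return float(sum(f.loglik for f in self.fits.values()))


def _prune_degenerate(df: pd.DataFrame, predictors: Sequence[str]) -> List[str]:
    keep = []
    for p in predictors:
        v = df[p].to_numpy(dtype=float)
        if np.nanstd(v) > 1e-12:
            keep.append(p)
    return keep


def fit_variant(
    data: StackedDataset,
    options: VariantOptions,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    **fit_kwargs,
):
    """Fit one variant to a stacked dataset.

    Returns a :class:`SeparateLandmarkFits` for variant 1 and a
    :class:`~cflandmark.survival.CoxFit` otherwise.  Variant 6 requires the
    mixed-model feature columns to be present in the records.
    """
    records = data.records
    v = options.variant
    if v == 6:
        require_mixed_features(records)
    if v == 1:
        fits: Dict[float, CoxFit] = {}
        fallback: List[float] = []
        for L in data.landmark_grid:
            sub = records[records["L"] == L].reset_index(drop=True)
            if len(sub) == 0:
                continue
            keep = _prune_degenerate(sub, predictors)
            spec = CoxModelSpec(
                terms=tuple(TermSpec(p, p) for p in keep),
                strata=None,
                cluster=options.cluster,
                ties=options.ties,
            )
            try:
                fits[float(L)] = fit_cox(sub, spec, variant="1", **fit_kwargs)
            except (ConvergenceError, RankDeficiencyError, np.linalg.LinAlgError):
                null_spec = CoxModelSpec(terms=(), strata=None, cluster=options.cluster, ties=options.ties)
                fits[float(L)] = fit_cox(sub, null_spec, variant="1-null", **fit_kwargs)
                fallback.append(float(L))
        return SeparateLandmarkFits(fits=fits, fallback_L=fallback)
    df = add_derived_columns(records, options, predictors)
    spec = build_variant(options, predictors)
    return fit_cox(df, spec, variant=str(v), **fit_kwargs)


def require_mixed_features(df: pd.DataFrame) -> None:
    """Raise if the two-stage mixed-model columns are absent."""
    missing = [c for c in MIXED_FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            "variant 6 requires mixed-model features; run the longitudinal "
            f"mixed stage first (missing columns: {missing})"
        )
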