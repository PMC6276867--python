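"""Synthetic longitudinal registry generator with a known survival truth.

Emulates the structure of a national cystic-fibrosis patient registry:
adults under (approximately) annual review during a fixed study window,
with continuous lung-function and anthropometric trajectories (correlated
random intercepts and slopes), persistent binary infection/comorbidity
states (discrete-time Markov chains at review times), zero-inflated counts
of days on intravenous antibiotics, a death hazard driven by the *current
latent* covariate values, lung transplantation as an intercurrent event,
and administrative censoring at the end of the study window.

Because the truth is known, every downstream stage (landmark construction,
Cox supermodel fitting, dynamic prediction, performance evaluation) can be
validated against it.  The module also exposes an oracle for the generative
conditional survival probability S(L + t | alive at L, covariate state).

Units: ages and times are decimal years; IV antibiotic variables are days
per year; weight kg; height cm; FEV1/FVC in percent predicted.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryParams",
    "BinaryStateParams",
    "IVDaysParams",
    "DiagnosisAgeDistribution",
    "HazardParams",
    "TransplantParams",
    "GeneratorConfig",
    "Registry",
    "simulate_registry",
    "oracle_survival",
    "oracle_survival_draws",
    "default_config",
    "ph_truth_config",
    "write_registry",
    "read_registry",
    "config_to_dict",
    "config_from_dict",
    "CONTINUOUS_VARIABLES",
    "BINARY_VARIABLES",
    "IV_VARIABLES",
    "TIME_DEPENDENT_VARIABLES",
    "BASELINE_VARIABLES",
]

# Covariate schema ----------------------------------------------------------

#: Continuous time-dependent variables with latent linear-in-age trajectories.
CONTINUOUS_VARIABLES: Tuple[str, ...] = ("fev1_pct", "fvc_pct", "height", "weight")

#: Binary time-dependent states evolving as discrete-time Markov chains.
BINARY_VARIABLES: Tuple[str, ...] = (
    "pseudomonas",
    "staph_aureus",
    "b_cepacia",
    "mrsa",
    "cfrd",
    "pancreatic_insufficiency",
    "other_hospitalization",
)

#: Zero-inflated annual counts of days on IV antibiotics.
IV_VARIABLES: Tuple[str, ...] = ("iv_days_hospital", "iv_days_home")

#: The 13 time-dependent predictors recorded at each annual review.
TIME_DEPENDENT_VARIABLES: Tuple[str, ...] = CONTINUOUS_VARIABLES + BINARY_VARIABLES + IV_VARIABLES

#: Baseline (time-fixed) predictors.
BASELINE_VARIABLES: Tuple[str, ...] = ("sex", "genotype_class", "diagnosis_age")


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid GeneratorConfig field '{name}': {msg}")


# Config dataclasses --------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryParams:
    """Latent linear trajectory x(age) = intercept + slope*(age-18) + a + b*(age-18).

    (a, b) are patient-level random intercept/slope, bivariate normal with
    standard deviations ``intercept_sd``/``slope_sd`` and correlation
    ``corr``; reviews observe the latent value plus N(0, residual_sd^2)
    measurement noise.  The death hazard depends on the latent value.
    """

    intercept: float
    slope: float
    intercept_sd: float
    slope_sd: float
    corr: float
    residual_sd: float
    floor: float = 1.0  # emitted measurements are clipped below at this value

    def validate(self, name: str) -> None:
        _require(self.intercept_sd >= 0, name, "intercept_sd must be >= 0")
        _require(self.slope_sd >= 0, name, "slope_sd must be >= 0")
        _require(self.residual_sd >= 0, name, "residual_sd must be >= 0")
        _require(-1.0 <= self.corr <= 1.0, name, "corr must be in [-1, 1]")


@dataclass(frozen=True)
class BinaryStateParams:
    """Two-state Markov chain updated at review times.

    ``p_on`` is the per-visit probability of switching 0 -> 1 and ``p_off``
    of 1 -> 0; the initial state is Bernoulli(initial_prevalence).
    """

    initial_prevalence: float
    p_on: float
    p_off: float

    def validate(self, name: str) -> None:
        for f in ("initial_prevalence", "p_on", "p_off"):
            v = getattr(self, f)
            _require(0.0 <= v <= 1.0, name, f"{f} must be a probability in [0, 1]")

    @property
    def stationary(self) -> float:
        """Long-run prevalence of the chain (initial prevalence if frozen)."""
        denom = self.p_on + self.p_off
        if denom == 0.0:
            return self.initial_prevalence
        return self.p_on / denom


@dataclass(frozen=True)
class IVDaysParams:
    """Zero-inflated annual days on IV antibiotics, redrawn at each review."""

    zero_prob: float
    mean_days: float

    def validate(self, name: str) -> None:
        _require(0.0 <= self.zero_prob <= 1.0, name, "zero_prob must be in [0, 1]")
        _require(self.mean_days >= 0.0, name, "mean_days must be >= 0")


@dataclass(frozen=True)
class DiagnosisAgeDistribution:
    """Mixture of infant diagnosis (exponential near birth) and adult tail."""

    infant_fraction: float = 0.85
    infant_mean: float = 0.5
    adult_onset: float = 16.0
    adult_mean: float = 8.0

    def validate(self, name: str) -> None:
        _require(0.0 <= self.infant_fraction <= 1.0, name, "infant_fraction in [0, 1]")
        _require(self.infant_mean > 0, name, "infant_mean must be > 0")
        _require(self.adult_mean > 0, name, "adult_mean must be > 0")


@dataclass(frozen=True)
class HazardParams:
    """Death hazard: lambda0(age) * exp(sum_v c_v (x_v - ref_v) + gamma * (year - mid)).

    ``ages``/``log_hazard`` define a piecewise-constant log baseline hazard
    of age (the rate at ``ages[k]`` applies on [ages[k], ages[k+1]), the
    first rate extends below ``ages[0]``, the last above ``ages[-1]``).
    ``coefficients`` maps covariate names to log-hazard-ratio slopes on the
    current latent value; ``reference`` gives the covariate values at which
    the baseline applies.  ``calendar_coefficient`` acts on calendar year
    centered at ``calendar_center``.
    """

    ages: Tuple[float, ...]
    log_hazard: Tuple[float, ...]
    coefficients: Dict[str, float] = field(default_factory=dict)
    reference: Dict[str, float] = field(default_factory=dict)
    calendar_coefficient: float = 0.0
    calendar_center: float = 2010.0

    def validate(self, name: str) -> None:
        _require(len(self.ages) == len(self.log_hazard), name, "ages and log_hazard must have equal length")
        _require(len(self.ages) >= 1, name, "need at least one baseline piece")
        _require(all(np.diff(self.ages) > 0), name, "ages must be strictly increasing")
        known = set(BASELINE_VARIABLES) | set(TIME_DEPENDENT_VARIABLES)
        for k in self.coefficients:
            _require(k in known, name, f"unknown covariate '{k}' in coefficients")


@dataclass(frozen=True)
class TransplantParams:
    """Transplant intensity exp(log_intercept + fev1_coefficient*(fev1-ref));
    after transplant the death hazard is constant exp(post_transplant_log_hazard)."""

    log_intercept: float
    fev1_coefficient: float = 0.0
    post_transplant_log_hazard: float = float(np.log(0.06))


@dataclass(frozen=True)
class GeneratorConfig:
    n_individuals: int
    seed: int
    study_window: Tuple[float, float] = (2005.0, 2016.0)
    visit_interval: float = 1.0
    visit_jitter_sd: float = 0.08
    birth_cohort_range: Tuple[float, float] = (1955.0, 1997.0)
    registry_start_year: float = 1995.0
    sex_female_prob: float = 0.48
    genotype_probs: Tuple[float, float, float] = (0.12, 0.38, 0.50)
    diagnosis_age_distribution: DiagnosisAgeDistribution = field(default_factory=DiagnosisAgeDistribution)
    trajectory_params: Dict[str, TrajectoryParams] = field(default_factory=dict)
    binary_state_params: Dict[str, BinaryStateParams] = field(default_factory=dict)
    iv_days_params: Dict[str, IVDaysParams] = field(default_factory=dict)
    hazard_params: HazardParams = field(
        default_factory=lambda: HazardParams(ages=(18.0,), log_hazard=(float(np.log(0.02)),))
    )
    transplant_params: Optional[TransplantParams] = None
    loss_rate: float = 0.0
    adult_entry_age: float = 18.0

    def validate(self) -> None:
        _require(self.n_individuals >= 0, "n_individuals", "must be >= 0")
        _require(self.study_window[0] < self.study_window[1], "study_window", "start must precede end")
        _require(self.visit_interval > 0, "visit_interval", "must be > 0")
        _require(self.visit_jitter_sd >= 0, "visit_jitter_sd", "must be >= 0")
        _require(self.birth_cohort_range[0] < self.birth_cohort_range[1], "birth_cohort_range", "start < end")
        _require(0.0 <= self.sex_female_prob <= 1.0, "sex_female_prob", "probability in [0, 1]")
        _require(abs(sum(self.genotype_probs) - 1.0) < 1e-9, "genotype_probs", "must sum to 1")
        _require(all(p >= 0 for p in self.genotype_probs), "genotype_probs", "must be nonnegative")
        _require(self.loss_rate >= 0, "loss_rate", "must be >= 0")
        self.diagnosis_age_distribution.validate("diagnosis_age_distribution")
        for v in CONTINUOUS_VARIABLES:
            _require(v in self.trajectory_params, "trajectory_params", f"missing variable '{v}'")
            self.trajectory_params[v].validate(f"trajectory_params[{v}]")
        for v in BINARY_VARIABLES:
            _require(v in self.binary_state_params, "binary_state_params", f"missing variable '{v}'")
            self.binary_state_params[v].validate(f"binary_state_params[{v}]")
        for v in IV_VARIABLES:
            _require(v in self.iv_days_params, "iv_days_params", f"missing variable '{v}'")
            self.iv_days_params[v].validate(f"iv_days_params[{v}]")
        self.hazard_params.validate("hazard_params")


@dataclass
class Registry:
    """Simulated registry: a patients table, an annual-reviews table and the
    configuration that produced them.

    ``truth`` holds the latent per-patient random effects behind the
    continuous trajectories (columns ``<var>_intercept``/``<var>_slope``,
    total values including the population terms); it exists only for
    simulated registries and is not part of the on-disk format.
    """

    patients: pd.DataFrame
    reviews: pd.DataFrame
    config_echo: GeneratorConfig
    truth: Optional[pd.DataFrame] = None


# Piecewise-constant baseline hazard ----------------------------------------


class PiecewiseConstantHazard:
    """lambda(age) piecewise constant on knots; exact integrals and inversion."""

    def __init__(self, ages: Sequence[float], log_hazard: Sequence[float]):
        self.knots = np.asarray(ages, dtype=float)
        self.rates = np.exp(np.asarray(log_hazard, dtype=float))

    def rate(self, age):
        idx = np.clip(np.searchsorted(self.knots, age, side="right") - 1, 0, len(self.rates) - 1)
        return self.rates[idx]

    def integral(self, a0, a1):
        """Exact integral of the hazard over [a0, a1] (vectorized)."""
        a0 = np.asarray(a0, dtype=float)
        a1 = np.asarray(a1, dtype=float)
        return self._cum(a1) - self._cum(a0)

    def _cum(self, a):
        # cumulative integral from knots[0]; constant first rate extends below
        a = np.asarray(a, dtype=float)
        k = self.knots
        r = self.rates
        widths = np.diff(k)
        cum_at_knots = np.concatenate([[0.0], np.cumsum(r[:-1] * widths)])
        idx = np.clip(np.searchsorted(k, a, side="right") - 1, 0, len(r) - 1)
        base = cum_at_knots[idx] + r[idx] * (a - k[idx])
        return base

    def invert_from(self, a0, target):
        """Smallest age a >= a0 with integral(a0, a) == target (vectorized)."""
        a0 = np.asarray(a0, dtype=float)
        target = np.asarray(target, dtype=float)
        c0 = self._cum(a0)
        goal = c0 + target
        k = self.knots
        r = self.rates
        widths = np.diff(k)
        cum_at_knots = np.concatenate([[0.0], np.cumsum(r[:-1] * widths)])
        idx = np.clip(np.searchsorted(cum_at_knots, goal, side="right") - 1, 0, len(r) - 1)
        # handle a0 below first knot: cumulative is negative there but formula
        # base = cum_at_knots[idx] + r[idx]*(a - k[idx]) still inverts linearly
        with np.errstate(divide="ignore", invalid="ignore"):
            age = k[idx] + (goal - cum_at_knots[idx]) / r[idx]
        age = np.maximum(age, a0)
        return age


# Default configurations ----------------------------------------------------


def default_config(n_individuals: int = 6000, seed: int = 0, **overrides) -> GeneratorConfig:
    """Registry-realistic defaults: adult CF cohort observed 2005-2015.

    Trajectory, prevalence and hazard magnitudes are chosen to produce a
    cohort of plausible adult lung-function decline (~1-1.5 %/yr FEV1),
    ~15-25% ten-year mortality among adults, and qualitative effect
    directions with higher FEV1%/FVC%/weight protective and B. cepacia,
    CF-related diabetes and hospital IV days harmful.
    """
    trajectories = {
        "fev1_pct": TrajectoryParams(75.0, -1.5, 18.0, 1.5, -0.2, 5.0, floor=10.0),
        "fvc_pct": TrajectoryParams(85.0, -1.2, 16.0, 1.2, -0.2, 5.0, floor=15.0),
        "height": TrajectoryParams(168.0, 0.0, 8.0, 0.0, 0.0, 1.0, floor=120.0),
        "weight": TrajectoryParams(58.0, 0.25, 9.0, 0.5, 0.1, 2.0, floor=30.0),
    }
    binaries = {
        "pseudomonas": BinaryStateParams(0.45, 0.12, 0.10),
        "staph_aureus": BinaryStateParams(0.35, 0.18, 0.25),
        "b_cepacia": BinaryStateParams(0.04, 0.01, 0.05),
        "mrsa": BinaryStateParams(0.05, 0.04, 0.25),
        "cfrd": BinaryStateParams(0.25, 0.06, 0.005),
        "pancreatic_insufficiency": BinaryStateParams(0.85, 0.01, 0.0),
        "other_hospitalization": BinaryStateParams(0.25, 0.25, 0.75),
    }
    iv = {
        "iv_days_hospital": IVDaysParams(0.55, 18.0),
        "iv_days_home": IVDaysParams(0.60, 14.0),
    }
    hazard = HazardParams(
        ages=(18.0, 30.0, 40.0, 50.0),
        log_hazard=tuple(np.log([0.006, 0.011, 0.020, 0.035])),
        coefficients={
            "fev1_pct": -0.045,
            "fvc_pct": -0.008,
            "weight": -0.025,
            "b_cepacia": 0.9,
            "cfrd": 0.4,
            "iv_days_hospital": 0.012,
            "iv_days_home": 0.004,
            "pseudomonas": 0.15,
            "mrsa": 0.35,
            "staph_aureus": 0.05,
            "other_hospitalization": 0.3,
            "pancreatic_insufficiency": 0.25,
            "sex": 0.15,
            "genotype_class": 0.05,
            "diagnosis_age": -0.01,
        },
        reference={"fev1_pct": 70.0, "fvc_pct": 80.0, "weight": 58.0, "height": 168.0},
        calendar_coefficient=-0.02,
        calendar_center=2010.5,
    )
    cfg = GeneratorConfig(
        n_individuals=n_individuals,
        seed=seed,
        trajectory_params=trajectories,
        binary_state_params=binaries,
        iv_days_params=iv,
        hazard_params=hazard,
        transplant_params=TransplantParams(
            log_intercept=float(np.log(0.004)), fev1_coefficient=-0.06
        ),
        loss_rate=0.0,
    )
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    cfg.validate()
    return cfg


def ph_truth_config(n_individuals: int = 2000, seed: int = 0, **overrides) -> GeneratorConfig:
    """A proportional-hazards truth: covariates frozen after baseline.

    All trajectory slopes and slope variances are zero, binary chains do not
    transition, IV days are identically zero, measurement noise is zero and
    there is no transplantation or calendar drift.  Conditional on the
    landmark-age covariates, the death hazard is then exactly
    lambda0(age) * exp(beta' x), i.e. the stratified Cox supermodel with
    last-observation-carried-forward covariates is correctly specified.
    Used for parameter-recovery and prediction-oracle checks.
    """
    trajectories = {
        "fev1_pct": TrajectoryParams(70.0, 0.0, 15.0, 0.0, 0.0, 0.0, floor=10.0),
        "fvc_pct": TrajectoryParams(80.0, 0.0, 14.0, 0.0, 0.0, 0.0, floor=15.0),
        "height": TrajectoryParams(168.0, 0.0, 8.0, 0.0, 0.0, 0.0, floor=120.0),
        "weight": TrajectoryParams(58.0, 0.0, 8.0, 0.0, 0.0, 0.0, floor=30.0),
    }
    binaries = {
        "pseudomonas": BinaryStateParams(0.45, 0.0, 0.0),
        "staph_aureus": BinaryStateParams(0.35, 0.0, 0.0),
        "b_cepacia": BinaryStateParams(0.05, 0.0, 0.0),
        "mrsa": BinaryStateParams(0.05, 0.0, 0.0),
        "cfrd": BinaryStateParams(0.25, 0.0, 0.0),
        "pancreatic_insufficiency": BinaryStateParams(0.85, 0.0, 0.0),
        "other_hospitalization": BinaryStateParams(0.25, 0.0, 0.0),
    }
    iv = {
        "iv_days_hospital": IVDaysParams(1.0, 0.0),
        "iv_days_home": IVDaysParams(1.0, 0.0),
    }
    hazard = HazardParams(
        ages=(18.0, 30.0, 40.0, 50.0),
        log_hazard=tuple(np.log([0.012, 0.020, 0.035, 0.055])),
        coefficients={
            "fev1_pct": -0.04,
            "weight": -0.03,
            "pseudomonas": 0.5,
            "cfrd": 0.5,
            "sex": 0.3,
        },
        reference={"fev1_pct": 70.0, "weight": 58.0},
        calendar_coefficient=0.0,
    )
    cfg = GeneratorConfig(
        n_individuals=n_individuals,
        seed=seed,
        trajectory_params=trajectories,
        binary_state_params=binaries,
        iv_days_params=iv,
        hazard_params=hazard,
        transplant_params=None,
        loss_rate=0.0,
        diagnosis_age_distribution=DiagnosisAgeDistribution(infant_fraction=1.0),
    )
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    cfg.validate()
    return cfg


def ph_single_landmark_config(n_individuals: int = 400_000, seed: int = 0, **overrides) -> GeneratorConfig:
    """Proportional-hazards truth concentrated on one landmark age (30).

    A narrow birth cohort (1975-76) makes every simulated adult reach
    landmark age 30 inside the study window with a full ten years of
    subsequent follow-up before the administrative end of study, so the
    baseline hazard is identified over the whole prediction horizon and a
    single-stratum supermodel fit has maximal precision.  Adult dynamics
    are simulated from age 24 to keep the visit grid short.  Used for
    prediction-oracle validation.
    """
    cfg = ph_truth_config(
        n_individuals,
        seed,
        birth_cohort_range=(1975.0, 1976.0),
        adult_entry_age=24.0,
        **overrides,
    )
    return cfg


# Simulation -----------------------------------------------------------------

_PATIENT_COLUMNS = [
    "id",
    "sex",
    "genotype_class",
    "birth",
    "diagnosis_age",
    "registry_entry_age",
    "death_age",
    "transplant_age",
    "loss_age",
]

_REVIEW_COLUMNS = ["patient_id", "age", "calendar_year"] + list(TIME_DEPENDENT_VARIABLES)


def simulate_registry(config: GeneratorConfig) -> Registry:
    """Simulate a registry: patients table + annual reviews table.

    Deterministic given ``config.seed``.  Latent continuous trajectories are
    linear in age with correlated random intercept/slope; binary states are
    Markov chains stepped at review times; the death time is drawn by
    inversion sampling from the hazard
    lambda0(age) * exp(linear predictor of the current latent values),
    with covariates held at their value at the start of each inter-review
    interval and the age-baseline integrated exactly within the interval.
    Transplantation competes with death; after transplant no further reviews
    are generated and the death hazard switches to a constant.  Observation
    ends at the earliest of death, loss to follow-up and the end of the
    study window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    if n == 0:
        return Registry(
            patients=pd.DataFrame(columns=_PATIENT_COLUMNS),
            reviews=pd.DataFrame(columns=_REVIEW_COLUMNS),
            config_echo=config,
        )

    start_year, end_year = config.study_window

    # demographics
    sex = rng.binomial(1, config.sex_female_prob, size=n)
    genotype = rng.choice(3, size=n, p=np.asarray(config.genotype_probs))
    birth = rng.uniform(*config.birth_cohort_range, size=n)
    dd = config.diagnosis_age_distribution
    infant = rng.random(n) < dd.infant_fraction
    diag_age = np.where(
        infant,
        np.minimum(rng.exponential(dd.infant_mean, size=n), 15.0),
        dd.adult_onset + rng.exponential(dd.adult_mean, size=n),
    )
    entry_age = np.maximum(diag_age, config.registry_start_year - birth)
    entry_age = np.maximum(entry_age, 0.0)

    sim_start = np.maximum(config.adult_entry_age, entry_age)
    sim_end = end_year - birth  # age at administrative end of study
    sim_end = np.maximum(sim_end, sim_start + 1e-9)

    # visit grid (jittered annual): K columns of ages per patient
    max_span = float(np.max(sim_end - sim_start))
    K = int(np.ceil(max_span / config.visit_interval * 1.15)) + 4
    gaps = config.visit_interval + rng.normal(0.0, config.visit_jitter_sd, size=(n, K))
    gaps = np.clip(gaps, 0.2, None)
    visit_age = sim_start[:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(gaps[:, :-1], axis=1)], axis=1
    )  # (n, K); visit_age[:,0] == sim_start

    # latent continuous trajectories at visit ages
    latent = {}
    rand_eff = {}
    for v in CONTINUOUS_VARIABLES:
        p = config.trajectory_params[v]
        cov = p.corr * p.intercept_sd * p.slope_sd
        cov_mat = np.array([[p.intercept_sd**2, cov], [cov, p.slope_sd**2]])
        ab = rng.multivariate_normal([0.0, 0.0], cov_mat, size=n, method="svd")
        a, b = ab[:, 0], ab[:, 1]
        rand_eff[v] = (a, b)
        t18 = visit_age - 18.0
        latent[v] = p.intercept + p.slope * t18 + a[:, None] + b[:, None] * t18

    # binary Markov chains at visit ages
    states = {}
    for v in BINARY_VARIABLES:
        p = config.binary_state_params[v]
        s = np.empty((n, K), dtype=np.int8)
        s[:, 0] = rng.random(n) < p.initial_prevalence
        for k in range(1, K):
            u = rng.random(n)
            prev = s[:, k - 1]
            s[:, k] = np.where(prev == 1, (u >= p.p_off).astype(np.int8), (u < p.p_on).astype(np.int8))
        states[v] = s

    # zero-inflated IV days, redrawn at each visit
    iv_vals = {}
    for v in IV_VARIABLES:
        p = config.iv_days_params[v]
        nonzero = rng.random((n, K)) >= p.zero_prob
        counts = rng.poisson(p.mean_days, size=(n, K)) if p.mean_days > 0 else np.zeros((n, K), dtype=int)
        iv_vals[v] = np.minimum(nonzero * counts, 366).astype(float)

    # linear predictor of the death hazard per inter-visit interval
    hz = config.hazard_params
    ref = hz.reference
    lp = np.zeros((n, K))
    for name, coef in hz.coefficients.items():
        r = ref.get(name, 0.0)
        if name in CONTINUOUS_VARIABLES:
            lp += coef * (latent[name] - r)
        elif name in BINARY_VARIABLES:
            lp += coef * (states[name] - r)
        elif name in IV_VARIABLES:
            lp += coef * (iv_vals[name] - r)
        elif name == "sex":
            lp += coef * (sex[:, None] - r)
        elif name == "genotype_class":
            lp += coef * (genotype[:, None] - r)
        elif name == "diagnosis_age":
            lp += coef * (diag_age[:, None] - r)
    if hz.calendar_coefficient != 0.0:
        year_at_visit = birth[:, None] + visit_age
        lp += hz.calendar_coefficient * (year_at_visit - hz.calendar_center)

    base = PiecewiseConstantHazard(hz.ages, hz.log_hazard)
    next_age = np.concatenate([visit_age[:, 1:], visit_age[:, -1:] + config.visit_interval], axis=1)
    base_int = base.integral(visit_age, next_age)  # (n, K) exact baseline integrals
    inc = np.exp(lp) * base_int
    cum = np.cumsum(inc, axis=1)

    e_death = rng.exponential(1.0, size=n)
    death_age = _invert_event_time(visit_age, next_age, lp, cum, e_death, base)

    # transplant (optional), competing with death while untransplanted
    if config.transplant_params is not None:
        tp = config.transplant_params
        fev_ref = ref.get("fev1_pct", 0.0)
        lp_tx = tp.log_intercept + tp.fev1_coefficient * (latent["fev1_pct"] - fev_ref)
        inc_tx = np.exp(lp_tx) * (next_age - visit_age)
        cum_tx = np.cumsum(inc_tx, axis=1)
        e_tx = rng.exponential(1.0, size=n)
        tx_age = _invert_event_time_linear(visit_age, next_age, lp_tx, cum_tx, e_tx)
        transplanted = tx_age < death_age
        post_rate = np.exp(tp.post_transplant_log_hazard)
        post_death = tx_age + rng.exponential(1.0 / post_rate, size=n)
        death_age = np.where(transplanted, post_death, death_age)
        tx_age = np.where(transplanted, tx_age, np.inf)
    else:
        tx_age = np.full(n, np.inf)

    # independent loss to follow-up
    if config.loss_rate > 0:
        loss_age = sim_start + rng.exponential(1.0 / config.loss_rate, size=n)
    else:
        loss_age = np.full(n, np.inf)

    obs_end = np.minimum.reduce([death_age, loss_age, sim_end])
    death_obs = np.where((death_age <= obs_end) & (death_age <= sim_end) & (death_age < loss_age), death_age, np.nan)
    loss_obs = np.where((loss_age < death_age) & (loss_age <= sim_end), loss_age, np.nan)
    tx_obs = np.where(tx_age < obs_end, tx_age, np.nan)

    patients = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": sex,
            "genotype_class": genotype,
            "birth": birth,
            "diagnosis_age": diag_age,
            "registry_entry_age": entry_age,
            "death_age": death_obs,
            "transplant_age": tx_obs,
            "loss_age": loss_obs,
        }
    )

    # emit reviews: visits strictly before min(death, transplant, loss, window end)
    review_end = np.minimum.reduce([death_age, tx_age, loss_age, sim_end])
    keep = visit_age < review_end[:, None]
    pid_mat = np.broadcast_to(np.arange(1, n + 1)[:, None], (n, K))
    rows = {
        "patient_id": pid_mat[keep],
        "age": visit_age[keep],
        "calendar_year": (birth[:, None] + visit_age)[keep],
    }
    for v in CONTINUOUS_VARIABLES:
        p = config.trajectory_params[v]
        noise = rng.normal(0.0, p.residual_sd, size=(n, K)) if p.residual_sd > 0 else 0.0
        obs = latent[v] + noise
        rows[v] = np.maximum(obs, p.floor)[keep]
    for v in BINARY_VARIABLES:
        rows[v] = states[v][keep].astype(int)
    for v in IV_VARIABLES:
        rows[v] = iv_vals[v][keep]
    reviews = pd.DataFrame(rows)[_REVIEW_COLUMNS]
    reviews = reviews.sort_values(["patient_id", "age"], kind="mergesort").reset_index(drop=True)

    truth_cols = {"patient_id": np.arange(1, n + 1)}
    for v in CONTINUOUS_VARIABLES:
        p = config.trajectory_params[v]
        a, b = rand_eff[v]
        truth_cols[f"{v}_intercept"] = p.intercept + a  # latent value at age 18
        truth_cols[f"{v}_slope"] = p.slope + b  # total latent slope per year
    truth = pd.DataFrame(truth_cols)

    return Registry(patients=patients, reviews=reviews, config_echo=config, truth=truth)


def _invert_event_time(t0, t1, lp, cum, e, base: PiecewiseConstantHazard):
    """Event age from piecewise hazard exp(lp_k)*lambda0(age) on [t0_k, t1_k)."""
    n, K = t0.shape
    prev_cum = np.concatenate([np.zeros((n, 1)), cum[:, :-1]], axis=1)
    k_idx = np.argmax(cum >= e[:, None], axis=1)
    has_event = cum[:, -1] >= e
    rows = np.arange(n)
    rem = (e - prev_cum[rows, k_idx]) / np.exp(lp[rows, k_idx])
    age = base.invert_from(t0[rows, k_idx], rem)
    age = np.minimum(age, t1[rows, k_idx])  # numerical guard
    return np.where(has_event, age, np.inf)


def _invert_event_time_linear(t0, t1, lp, cum, e):
    """Event age for a hazard constant within each interval (rate exp(lp_k))."""
    n, K = t0.shape
    prev_cum = np.concatenate([np.zeros((n, 1)), cum[:, :-1]], axis=1)
    k_idx = np.argmax(cum >= e[:, None], axis=1)
    has_event = cum[:, -1] >= e
    rows = np.arange(n)
    rem = (e - prev_cum[rows, k_idx]) / np.exp(lp[rows, k_idx])
    age = t0[rows, k_idx] + rem
    age = np.minimum(age, t1[rows, k_idx])
    return np.where(has_event, age, np.inf)


# Survival oracle ------------------------------------------------------------


def _conditional_slope(value: float, L: float, p: TrajectoryParams) -> float:
    """Expected total slope of the latent trajectory given its value at age L."""
    u = L - 18.0
    resid = value - (p.intercept + p.slope * u)
    var = p.intercept_sd**2 + 2 * u * p.corr * p.intercept_sd * p.slope_sd + (u * p.slope_sd) ** 2
    if var <= 0:
        return p.slope
    cov_b = p.corr * p.intercept_sd * p.slope_sd + u * p.slope_sd**2
    return p.slope + cov_b / var * resid


def oracle_survival_draws(
    patient_state: Dict[str, float],
    landmark_age: float,
    t: float,
    config: GeneratorConfig,
    n_draws: int = 100_000,
    inner_seed: int = 20_200_518,
) -> np.ndarray:
    """Per-draw conditional survival probabilities under the generative truth.

    Continuous covariates follow their conditional-mean latent trajectory
    given the value supplied in ``patient_state``; binary states are evolved
    by their Markov chains and IV-day counts redrawn per interval, both
    marginalized by Monte Carlo with a fixed inner seed.  Each draw yields
    exp(-integrated hazard); the oracle estimate is the mean over draws.
    Requires an inactive transplant process (the landmark analyses treat
    post-transplant deaths as events of the same process, which this
    conditional oracle does not model).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if config.transplant_params is not None:
        raise ValueError("oracle_survival requires a config without transplantation")
    if t == 0:
        return np.ones(1)
    rng = np.random.default_rng(inner_seed)
    hz = config.hazard_params
    ref = hz.reference
    base = PiecewiseConstantHazard(hz.ages, hz.log_hazard)
    dt = config.visit_interval
    n_steps = int(np.ceil(t / dt - 1e-12))
    edges = np.minimum(landmark_age + dt * np.arange(n_steps + 1), landmark_age + t)
    widths_base = base.integral(edges[:-1], edges[1:])  # (n_steps,)

    lp = np.zeros((n_draws, n_steps))
    for name, coef in hz.coefficients.items():
        r = ref.get(name, 0.0)
        if name in CONTINUOUS_VARIABLES:
            v0 = float(patient_state[name])
            slope = _conditional_slope(v0, landmark_age, config.trajectory_params[name])
            path = v0 + slope * (edges[:-1] - landmark_age)
            lp += coef * (path - r)[None, :]
        elif name in BINARY_VARIABLES:
            p = config.binary_state_params[name]
            s = np.full(n_draws, int(round(float(patient_state[name]))), dtype=np.int8)
            for k in range(n_steps):
                if k > 0 and (p.p_on > 0 or p.p_off > 0):
                    u = rng.random(n_draws)
                    s = np.where(s == 1, (u >= p.p_off).astype(np.int8), (u < p.p_on).astype(np.int8))
                lp[:, k] += coef * (s - r)
        elif name in IV_VARIABLES:
            p = config.iv_days_params[name]
            v0 = float(patient_state[name])
            for k in range(n_steps):
                if k == 0:
                    vals = np.full(n_draws, v0)
                else:
                    nz = rng.random(n_draws) >= p.zero_prob
                    vals = nz * (rng.poisson(p.mean_days, size=n_draws) if p.mean_days > 0 else 0)
                lp[:, k] += coef * (np.minimum(vals, 366) - r)
        else:  # baseline variables
            lp += coef * (float(patient_state[name]) - r)
    if hz.calendar_coefficient != 0.0:
        year0 = float(patient_state["calendar_year"])
        years = year0 + (edges[:-1] - landmark_age)
        lp += hz.calendar_coefficient * (years - hz.calendar_center)[None, :]

    H = np.sum(np.exp(lp) * widths_base[None, :], axis=1)
    return np.exp(-H)


def oracle_survival(
    patient_state: Dict[str, float],
    landmark_age: float,
    t: float,
    config: GeneratorConfig,
    n_draws: int = 100_000,
    inner_seed: int = 20_200_518,
) -> float:
    """Generative conditional survival S(landmark_age + t | state at landmark)."""
    return float(np.mean(oracle_survival_draws(patient_state, landmark_age, t, config, n_draws, inner_seed)))


# Registry I/O ---------------------------------------------------------------


def write_registry(registry: Registry, out_dir) -> None:
    """Write patients.csv, reviews.csv and config.json to ``out_dir``."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry.patients.to_csv(out / "patients.csv", index=False)
    registry.reviews.to_csv(out / "reviews.csv", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(config_to_dict(registry.config_echo), fh, indent=2)


def read_registry(in_dir) -> Registry:
    """Read a registry written by :func:`write_registry` (config optional)."""
    d = pathlib.Path(in_dir)
    patients = pd.read_csv(d / "patients.csv", float_precision="round_trip")
    reviews = pd.read_csv(d / "reviews.csv", float_precision="round_trip")
    cfg_path = d / "config.json"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = config_from_dict(json.load(fh))
    else:
        config = None
    return Registry(patients=patients, reviews=reviews, config_echo=config)


def config_to_dict(config: GeneratorConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    d["study_window"] = tuple(d["study_window"])
    d["birth_cohort_range"] = tuple(d["birth_cohort_range"])
    d["genotype_probs"] = tuple(d["genotype_probs"])
    d["diagnosis_age_distribution"] = DiagnosisAgeDistribution(**d["diagnosis_age_distribution"])
    d["trajectory_params"] = {k: TrajectoryParams(**v) for k, v in d["trajectory_params"].items()}
    d["binary_state_params"] = {k: BinaryStateParams(**v) for k, v in d["binary_state_params"].items()}
    d["iv_days_params"] = {k: IVDaysParams(**v) for k, v in d["iv_days_params"].items()}
    hz = dict(d["hazard_params"])
    hz["ages"] = tuple(hz["ages"])
    hz["log_hazard"] = tuple(hz["log_hazard"])
    d["hazard_params"] = HazardParams(**hz)
    if d.get("transplant_params") is not None:
        d["transplant_params"] = TransplantParams(**d["transplant_params"])
    cfg = GeneratorConfig(**d)
    cfg.validate()
    return cfg
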