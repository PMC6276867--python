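"""Shared fixtures: hand-written toy registries and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

import cflandmark as cf


@pytest.fixture(scope="session")
def toy_registry():
    """Five patients with hand-checkable eligibility and outcomes.

    Study window 2005-2016 (administrative censoring at end of 2015).

    P1 birth 1980, infant diagnosis, never dies: ages 25..36 in window.
    P2 birth 1985, dies at age 27.3 (in 2012.3).
    P3 birth 1982, transplanted at 25, dies at 28 (post-transplant death).
    P4 birth 1970, diagnosed as an adult at 30.
    P5 birth 1987, lost to follow-up at age 26.
    """
    patients = pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5],
            "sex": [0, 1, 0, 1, 0],
            "genotype_class": [2, 2, 1, 0, 2],
            "birth": [1980.0, 1985.0, 1982.0, 1970.0, 1987.0],
            "diagnosis_age": [0.5, 1.0, 0.8, 30.0, 0.3],
            "registry_entry_age": [15.0, 10.0, 13.0, 30.0, 8.0],
            "death_age": [np.nan, 27.3, 28.0, np.nan, np.nan],
            "transplant_age": [np.nan, np.nan, 25.0, np.nan, np.nan],
            "loss_age": [np.nan, np.nan, np.nan, np.nan, 26.0],
        }
    )
    rows = []

    def reviews_for(pid, birth, ages, fev_start):
        for j, a in enumerate(ages):
            rows.append(
                {
                    "patient_id": pid,
                    "age": a,
                    "calendar_year": birth + a,
                    "fev1_pct": fev_start - 2.0 * j,
                    "fvc_pct": 90.0 - j,
                    "height": 170.0,
                    "weight": 55.0 + 0.5 * j,
                    "pseudomonas": j % 2,
                    "staph_aureus": 0,
                    "b_cepacia": 0,
                    "mrsa": 0,
                    "cfrd": 0,
                    "pancreatic_insufficiency": 1,
                    "other_hospitalization": 0,
                    "iv_days_hospital": 3.0 * j,
                    "iv_days_home": 0.0,
                }
            )

    reviews_for(1, 1980.0, [18.2, 19.1, 20.3, 22.0, 24.5, 26.1, 30.0], 85.0)
    reviews_for(2, 1985.0, [18.5, 20.1, 22.2, 24.9, 26.5], 70.0)
    reviews_for(3, 1982.0, [18.1, 20.0, 22.5, 24.4], 60.0)
    reviews_for(4, 1970.0, [30.1, 32.0, 35.5, 40.2], 75.0)
    reviews_for(5, 1987.0, [18.0, 20.5, 23.1, 25.2], 95.0)
    reviews = pd.DataFrame(rows)
    return cf.Registry(patients=patients, reviews=reviews, config_echo=None)


TOY_WINDOW = (2005.0, 2016.0)


@pytest.fixture(scope="session")
def small_registry():
    """Small realistic synthetic registry (n=400)."""
    return cf.simulate_registry(cf.default_config(400, seed=11))


@pytest.fixture(scope="session")
def small_stacked(small_registry):
    return cf.build_stacked_dataset(small_registry)


@pytest.fixture(scope="session")
def ph_registry():
    """Proportional-hazards truth (frozen covariates), n=800."""
    return cf.simulate_registry(cf.ph_truth_config(800, seed=7))


@pytest.fixture(scope="session")
def ph_stacked(ph_registry):
    return cf.build_stacked_dataset(ph_registry)
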