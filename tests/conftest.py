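"""Shared fixtures: toy tariffs, reference coefficient sets, cached cohorts."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

import qolmap
from qolmap.instruments import ValueSet
from qolmap.synthetic import CohortSpec, generate_cohort

# silence statsmodels optimizer chatter in the suite
warnings.filterwarnings("ignore", module="statsmodels")

#: reference coefficient set of the packaged scale-score linear model
#: (random-intercept linear model on the utility scale)
REFERENCE_LINEAR = {
    "intercept": 0.2993,
    "physical": 0.0021,
    "role": 0.0011,
    "emotional": 0.0025,
    "cognitive": 0.0005,
    "social": 0.0006,
    "pain": -0.0023,
    "insomnia": -0.0005,
}

#: reference link-scale coefficient set of the disutility beta model
REFERENCE_BETA = {
    "intercept": 2.081,
    "global_health": -0.004,
    "physical": -0.018,
    "role": -0.010,
    "emotional": -0.015,
    "cognitive": -0.005,
    "pain": 0.014,
    "insomnia": 0.005,
    "financial": 0.007,
}


@pytest.fixture(scope="session")
def toy_value_set() -> ValueSet:
    """Purely additive toy tariff: level 2 costs 0.1, level 3 costs 0.3."""
    dec = {d: {1: 0.0, 2: 0.1, 3: 0.3} for d in qolmap.instruments.EQ5D_DOMAINS}
    return ValueSet(name="toy", constant=1.0, decrements=dec)


@pytest.fixture(scope="session")
def nl_value_set() -> ValueSet:
    return qolmap.load_value_set("NL")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Full-size synthetic cohort under default study conditions."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort) -> pd.DataFrame:
    out = default_cohort.copy()
    scores = qolmap.score_qlqc30(out)
    for c in scores.columns:
        out[c] = scores[c]
    return out


@pytest.fixture(scope="session")
def small_scored_cohort() -> pd.DataFrame:
    """Small cohort (fast fits) with scales attached."""
    out = generate_cohort(CohortSpec(seed=11, n_rows=500, n_patients=125))
    scores = qolmap.score_qlqc30(out)
    for c in scores.columns:
        out[c] = scores[c]
    return out


def best_record() -> dict:
    """All functional items at their best, symptoms absent, global excellent."""
    rec = {f"q{i}": 1 for i in range(1, 29)}
    rec.update(q29=7, q30=7)
    return rec


def worst_record() -> dict:
    rec = {f"q{i}": 4 for i in range(1, 29)}
    rec.update(q29=1, q30=1)
    return rec
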