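"""Shared fixtures.

The calibrated S1 scenario and its simulated cohorts are expensive
(deterministic calibration plus large-n simulation), so they are built
once per session and shared across test modules.
"""

import numpy as np
import pytest

from latemort.cohort import (
    PostRelapseHazard,
    ScenarioConfig,
    TransitionHazard,
    s1_lifetables,
    s1_scenario,
    sample_cohort,
)
from latemort.lifetables import LifeTable, LifeTableCollection


@pytest.fixture(scope="session")
def tables_s1():
    return s1_lifetables()


@pytest.fixture(scope="session")
def s1(tables_s1):
    scenario, report = s1_scenario()
    return scenario


@pytest.fixture(scope="session")
def s1_report():
    _, report = s1_scenario()
    return report


@pytest.fixture(scope="session")
def cohort_100k(s1, tables_s1):
    return sample_cohort(s1, tables_s1, 100_000, seed=1)


@pytest.fixture(scope="session")
def cohort_50k_seed2(s1, tables_s1):
    return sample_cohort(s1, tables_s1, 50_000, seed=2)


def constant_table(q: float, country: str = "XX", sex: str = "male") -> LifeTable:
    """Life table with the same annual death probability in every cell."""
    return LifeTable(
        sex=sex, country=country, age_start=0, year_start=1995,
        q=np.full((111, 45), q),
    )


def flat_tables(q: float) -> LifeTableCollection:
    """Constant-hazard tables for the test country and the S1 countries."""
    from latemort.cohort import S1_COUNTRIES

    return LifeTableCollection(
        [
            constant_table(q, country=c, sex=s)
            for c in list(S1_COUNTRIES) + ["XX"]
            for s in ("male", "female")
        ]
    )


def simple_scenario(
    rel: float = 0.0,
    exc: float = 0.0,
    post: float = 0.0,
    ltfu: float = 0.0,
    entry: tuple[float, float] = (2013.0, 2013.0),
    closure: float = 2017.0,
    age: int = 50,
    **post_kwargs,
) -> ScenarioConfig:
    """Single-stratum scenario with constant hazards (closed-form oracle)."""
    return ScenarioConfig(
        name="simple",
        sex_probs={"male": 1.0, "female": 0.0},
        band_probs=np.array([0.0, 1.0, 0.0, 0.0]) if 45 <= age < 55
        else np.array([1.0, 0.0, 0.0, 0.0]),
        band_ages=[np.array([30]), np.array([age]), np.array([60]), np.array([70])],
        band_age_weights=[np.ones(1)] * 4,
        entry_periods=[(entry[0], entry[1], 1.0)],
        country_probs={"XX": 1.0},
        subtype_probs={"MDS_noEB": 1.0, "MDS_EB": 0.0, "sAML": 0.0},
        donor_probs={"HLA_id_sibling": 1.0, "other": 0.0},
        conditioning_probs={"MAC": 1.0, "RIC": 0.0, "missing": 0.0},
        relapse=TransitionHazard(
            breaks=np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0]),
            rates=np.full(6, rel),
        ),
        excess=TransitionHazard(
            breaks=np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0]),
            rates=np.full(6, exc),
        ),
        post_relapse=PostRelapseHazard(
            breaks=np.array([0.0, 0.25, 0.5, 1.0, 2.0]),
            rates=np.full(5, post),
            **post_kwargs,
        ),
        ltfu_rate=ltfu,
        closure=closure,
    )
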