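"""Shared fixtures: small synthetic cohorts and one reusable fast-mode fit.

Fixture sizes are chosen so the whole suite runs on one CPU inside the
budget; the scientific content of each test does not depend on the sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

import ticjoint as tj
from ticjoint.data import CohortData
from ticjoint.inference import EngineConfig, fit


def make_cohort(n_patients: int, seed: int) -> CohortData:
    """Full generated cohort, including never-measured patients.

    Recovery experiments must fit the population the generator produced:
    dropping patients without marker records (as the complete-case clinical
    pipeline does) is informative selection, because very early deaths are
    strongly enriched among the never-measured.
    """
    cfg = tj.default_cohort_config(n_patients=n_patients, seed=seed)
    cov, lon, sur, _ = tj.generate_cohort(cfg)
    return CohortData(covariates=cov, longitudinal=lon, survival=sur)


@pytest.fixture(scope="session")
def small_cohort() -> CohortData:
    """120 patients with a handful of deaths."""
    return make_cohort(120, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One fast-mode fit shared by reporting/inference tests."""
    engine = EngineConfig(mode="fast", seed=5, chains=4, draws=250)
    return fit(small_cohort, engine=engine)


@pytest.fixture(scope="session")
def recovery_fit():
    """Fast-mode fit of an n=1000 cohort generated at the published truth;
    shared by the recovery, coefficient and slope-distribution checks."""
    data = make_cohort(1000, seed=1)
    engine = EngineConfig(mode="fast", seed=5, chains=4, draws=250)
    return fit(data, engine=engine)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
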