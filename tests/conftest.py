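"""Shared fixtures: a small synthetic cohort and a trained joint model.

Session scope keeps the expensive artifacts (cohort generation, feature
selection, network training) shared across test modules; everything is
seeded, so the fixtures are reproducible bit-for-bit.
"""

import numpy as np
import pandas as pd
import pytest

from protdx.cohortio import make_stratified_kfold
from protdx.featselect import select_features
from protdx.syncohort import SimulationConfig, generate_cohort
from protdx import jointnet


SMALL_CONFIG = dict(
    n_participants=600,
    n_proteins=300,
    n_sites=4,
    planted_proteins_per_condition=10,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = generate_cohort(SimulationConfig(**SMALL_CONFIG))
    return cohort, truth


@pytest.fixture(scope="session")
def small_split(small_cohort):
    cohort, _ = small_cohort
    plan = make_stratified_kfold(cohort, k=5, seed=0)
    return plan


@pytest.fixture(scope="session")
def small_panel(small_cohort, small_split):
    cohort, _ = small_cohort
    tr, va, _ = small_split.folds[0]
    return select_features(
        cohort, pd.Index(tr).append(pd.Index(va)), seed=0,
        screen_top_n=150, n_rounds=120,
    )


@pytest.fixture(scope="session")
def small_model(small_cohort, small_split, small_panel):
    cohort, _ = small_cohort
    spec = jointnet.JointModelSpec(
        hidden=(64, 32), embedding_dim=16, max_epochs=60, seed=3
    )
    return jointnet.train(spec, cohort, small_panel, small_split.folds[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
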