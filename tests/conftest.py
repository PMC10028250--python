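"""Shared fixtures: synthetic walker recordings and cohorts.

Everything is generated programmatically and seeded; session scope keeps
the expensive objects (cohorts, fitted models) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitscreen._walker import WalkerConfig, synthesize_walker
from gaitscreen.model import SubjectModel, split_dataset
from gaitscreen.synthetic import generate_cohort


@pytest.fixture(scope="session")
def walker():
    """Default 50 Hz walker recording with ground truth."""
    return synthesize_walker()


@pytest.fixture(scope="session")
def walker_hires():
    """Densely sampled walker for high-fidelity profile comparisons."""
    return synthesize_walker(WalkerConfig(frame_rate=200.0, stride_frames=160))


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (58 subjects, delay subgroup injected)."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def age_fit(cohort):
    """Age model fitted on the cohort's NBW training strides."""
    train, _, _ = split_dataset(cohort.strides, seed=1)
    model = SubjectModel.from_dataframe(train, outcome="age")
    return model.fit(draws=1000, tune=500, chains=4, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
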