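"""Shared fixtures: one desk-scale simulated study reused across the suite."""

import numpy as np
import pytest
from hypothesis import settings

from fcbench import experiments

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """Desk-scale two-site study (20 + 12 subjects, 20 regions, 5 planted edges)."""
    return experiments.build_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def covs_s3(study):
    """Ledoit-Wolf covariances after denoising with aCompCor(50%)+12HMP."""
    cleaned = experiments.clean_study(study, (3,))[3]
    return experiments.covariances(cleaned)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
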