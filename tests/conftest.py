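import numpy as np
import pytest

from linzpk import (
    PopulationParameters,
    SyntheticCohortConfig,
    analysis_subset,
    generate_cohort,
)


@pytest.fixture(scope="session")
def params():
    return PopulationParameters()


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-subject synthetic TDM cohort with ground truth (session cache)."""
    cfg = SyntheticCohortConfig(n_subjects=24, seed=7)
    ds, truth = generate_cohort(cfg)
    return analysis_subset(ds), truth


@pytest.fixture(scope="session")
def study_cohort():
    """A full-size (103-subject) cohort at the published generating values."""
    cfg = SyntheticCohortConfig(n_subjects=103, seed=11)
    ds, truth = generate_cohort(cfg)
    return analysis_subset(ds), truth
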