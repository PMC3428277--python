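import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adirshort as a

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ALL_ITEMS = list(range(1, a.instrument.N_ITEMS + 1))


def retained_items(sheets):
    excluded = a.identify_excluded_items(sheets)
    return [i for i in ALL_ITEMS if i not in excluded]


@pytest.fixture(scope="session")
def default_cohort():
    """The study-shaped cohort (891 cases / 75 controls) at a fixed seed."""
    return a.generate_cohort(a.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    return a.recode_cohort(default_cohort, retained_items(default_cohort))


@pytest.fixture(scope="session")
def default_model(default_matrix):
    return a.fit_adtree(default_matrix)


@pytest.fixture(scope="session")
def small_matrix():
    """A light cohort for cross-validation-heavy tests."""
    sheets = a.generate_cohort(a.CohortConfig(n_cases=120, n_controls=40, seed=7))
    return a.recode_cohort(sheets, retained_items(sheets))


def make_sheet(subject_id="s1", age_months=96, verbal=True, diagnosis=a.AUTISM,
               answers=None):
    if answers is None:
        answers = {i: 0 for i in ALL_ITEMS}
    return a.AnswerSheet(
        subject_id=subject_id,
        age_months=age_months,
        verbal=verbal,
        diagnosis=diagnosis,
        answers=answers,
    )


def matrix_from_arrays(scores, labels, item_ids=None):
    scores = np.asarray(scores)
    item_ids = item_ids or list(range(1, scores.shape[1] + 1))
    return a.RecodedMatrix(
        subject_ids=[f"r{i}" for i in range(scores.shape[0])],
        item_ids=list(item_ids),
        scores=scores,
        labels=np.asarray(labels),
    )
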