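import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fuzzyslim as fs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def taxonomy():
    return fs.load_taxonomy()


@pytest.fixture(scope="session")
def tasks():
    return fs.load_task_analysis()


@pytest.fixture(scope="session")
def case_sheet(tasks):
    return fs.load_ratings(tasks=tasks)


@pytest.fixture(scope="session")
def case_results(tasks, case_sheet, taxonomy):
    return fs.assess(tasks, case_sheet, taxonomy)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220225)
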