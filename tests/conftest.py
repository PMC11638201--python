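import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mmpatterns.cohort import Cohort
from mmpatterns.registry import DEFAULT_REGISTRY
from mmpatterns.simulate import SyntheticConfig, generate

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_row(pid="P1", sbp=120.0, dbp=70.0, self_htn=False, diseases=(),
             **cov):
    """One well-formed cohort row as a dict (all flags 0 unless listed)."""
    row = {
        "participant_id": pid, "sbp": sbp, "dbp": dbp,
        "self_reported_hypertension": self_htn,
        "sex": cov.pop("sex", "female"), "age": cov.pop("age", 50),
    }
    for code in DEFAULT_REGISTRY.self_report_codes:
        row[code] = code in diseases
    row.update(cov)
    return row


def make_cohort(rows):
    return Cohort(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's stated default world (4 planted blocks, n=20,000)."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A smaller synthetic cohort for cheap end-to-end tests."""
    return generate(SyntheticConfig(n=4000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_disease_matrix(rng):
    """Random 200 x 26 disease matrix (no planted structure)."""
    from mmpatterns.diagnosis import CHL_2018, DiseaseMatrix

    values = (rng.random((200, 26)) < 0.3).astype(np.int8)
    # guarantee no constant columns
    values[0, :] = 1
    values[1, :] = 0
    return DiseaseMatrix(
        values=values,
        row_ids=np.array([f"P{i}" for i in range(200)]),
        criterion=CHL_2018, registry=DEFAULT_REGISTRY)
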