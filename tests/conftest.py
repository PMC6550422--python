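import pytest

from cepsb.synthetic import CohortConfig, calibrate_default_model, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One error-free default cohort (370 stays, 52 cases), shared."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def calibrated_model():
    return calibrate_default_model()


@pytest.fixture()
def small_config():
    """A reduced configuration for fast file/CLI tests."""
    return CohortConfig(
        n_stays_per_center={"A": 40, "B": 30},
        cepsb_per_center={"A": 6, "B": 5},
        excluded_per_center={"A": 2, "B": 1},
        seed=7,
    )
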