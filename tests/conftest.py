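import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort():
    """One small mixed cohort with a negative treatment effect on STs."""
    from pavca import CohortDesign, simulate_cohort

    design = CohortDesign(
        n_per_cell=4,
        seed=7,
        sessions_acquisition=(1, 5),
        sessions_rescreen=(6, 7),
        sessions_test=(8, 9),
        treatment_onset_session=8,
        treat_shifts={"ST": -0.5},
    )
    trials, truth = simulate_cohort(design)
    return design, trials, truth
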