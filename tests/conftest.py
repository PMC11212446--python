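import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noisytab.synthetic_data import CohortSpec, generate_cohort, split_cohort
from noisytab.preprocess import apply_preprocess, fit_preprocess

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 1,200-presentation cohort with the default EHR-like shape."""
    return generate_cohort(CohortSpec(n_samples=1200, n_features=8, seed=7))


@pytest.fixture(scope="session")
def prepared_splits(small_cohort):
    """Preprocessed 60/20/20 splits of the small cohort."""
    train, val, test = split_cohort(small_cohort, seed=3)
    state = fit_preprocess(train)
    return (
        apply_preprocess(state, train),
        apply_preprocess(state, val),
        apply_preprocess(state, test),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
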