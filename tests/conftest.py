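import numpy as np
import pytest

from asfemg import pipeline, synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def windows():
    """100 random 90-sample windows on a millivolt-like scale."""
    r = np.random.default_rng(777)
    return [0.3 * r.standard_normal(90) for _ in range(100)]


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject cohort at reduced repetition count, shared across tests."""
    return synth.generate_cohort(4, seed=11, reps=6)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """ASF-14NP features for the non-paretic side of the small cohort."""
    X, y, groups, names = pipeline.cohort_features(small_cohort, "non-paretic", "ASF14NP")
    return X, y, groups, names
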