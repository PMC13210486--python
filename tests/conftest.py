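import numpy as np
import pytest

from nocisense.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject cohort with the full protocol; shared across tests."""
    cfg = CohortConfig(n_subjects=4, seed=11)
    sessions, truth = generate_cohort(cfg)
    return cfg, sessions, truth


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from nocisense.features import build_feature_table

    _, sessions, _ = small_cohort
    return build_feature_table(sessions)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
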