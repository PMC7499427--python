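import numpy as np
import pytest

from hepanode import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 patients, moderate class separation; shared across read-only tests."""
    return generate_cohort(CohortConfig(n_patients=20, seed=42))


@pytest.fixture(scope="session")
def separated_cohort():
    """40 patients with a wide benign/malignant phenotype gap."""
    return generate_cohort(CohortConfig(n_patients=40, class_separation=1.5, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
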