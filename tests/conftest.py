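import numpy as np
import pytest

import isoemg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-class cohort (2 + 2 subjects, 2 trials) for integration
    tests that do not need the full-size study design."""
    trials, meta = isoemg.generate_cohort(
        n_amateur=2, n_professional=2, n_trials=2, seed=42
    )
    return trials, meta


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    eps, log = isoemg.detect_cohort(small_cohort[0])
    return eps, log


@pytest.fixture(scope="session")
def small_table(small_epochs):
    return isoemg.extract_features(small_epochs[0], 1000.0)
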