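import numpy as np
import pytest

from kuq.synthetic_ehr import CohortConfig, generate_cohort, default_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def small_cohort(vocab):
    """Fifty synthetic episodes; enough structure for corruption tests."""
    cfg = CohortConfig(n_patients=50, seed=42)
    return generate_cohort(cfg, vocab)


@pytest.fixture(scope="session")
def blobs():
    """Linearly separable 2-D two-class data for training sanity checks."""
    rng = np.random.default_rng(3)
    n = 120
    x0 = rng.normal((-2.0, 0.0), 0.4, size=(n // 2, 2))
    x1 = rng.normal((2.0, 0.0), 0.4, size=(n // 2, 2))
    X = np.vstack([x0, x1])
    y = np.repeat([0, 1], n // 2)
    return X, y
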