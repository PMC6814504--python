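import numpy as np
import pytest

from twinfactor import BiometricParams, simulate_univariate_twin_sample


@pytest.fixture(scope="session")
def ae_params():
    return BiometricParams(a=np.sqrt(0.64), e=np.sqrt(0.36))


@pytest.fixture(scope="session")
def ae_study_small(ae_params):
    """Tiny AE sample (10 pairs per group) for oracle-equivalence checks."""
    return simulate_univariate_twin_sample(ae_params, 10, 10, seed=42)


@pytest.fixture(scope="session")
def ae_study_medium(ae_params):
    """Moderate AE sample for recovery smoke tests (kept small for speed)."""
    return simulate_univariate_twin_sample(ae_params, 4000, 4000, seed=7)
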