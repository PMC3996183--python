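import numpy as np
import pytest

import strokebci as sb


@pytest.fixture(scope="session")
def healthy_session():
    """One default healthy synthetic session (beta-band ERD over C3)."""
    return sb.generate_session(sb.make_profile("healthy", seed=5), "H1")


@pytest.fixture(scope="session")
def healthy_tensor(healthy_session):
    """The session pushed through mirroring, filter bank and epoching."""
    return sb.preprocess_session(healthy_session)


@pytest.fixture(scope="session")
def fitted_csp(healthy_tensor):
    return sb.FilterBankCSP().fit(healthy_tensor)


@pytest.fixture(scope="session")
def healthy_features(fitted_csp, healthy_tensor):
    return fitted_csp.transform(healthy_tensor)


@pytest.fixture(scope="session")
def tiny_session():
    """A short low-rate session for I/O and structural tests."""
    prof = sb.make_profile("healthy", n_trials_per_class=2, trial_length=1.0,
                           fs=96.0, seed=3)
    return sb.generate_session(prof, "T1")


def random_covariance(rng, n):
    a = rng.standard_normal((n, 2 * n))
    return a @ a.T / (2 * n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
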