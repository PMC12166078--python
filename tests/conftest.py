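import numpy as np
import pytest

from rhythmlink import presets, sem


@pytest.fixture(scope="session")
def stage3_spec():
    """Three-factor CFA with published standardised values as starts."""
    return presets.stage3_spec()


@pytest.fixture(scope="session")
def stage3_sigma(stage3_spec):
    """Population covariance implied by the published parameterisation."""
    return sem.implied_covariance(stage3_spec, stage3_spec.start_vector())


@pytest.fixture(scope="session")
def stage3_sample(stage3_spec, stage3_sigma):
    """One multivariate-normal sample of the analysis size (N = 5873)."""
    rng = np.random.default_rng(20240301)
    X = rng.multivariate_normal(np.zeros(stage3_sigma.shape[0]), stage3_sigma,
                                size=presets.STAGE3_N)
    return X


@pytest.fixture(scope="session")
def stage3_fit(stage3_spec, stage3_sample):
    """ML refit of the three-factor model to the simulated sample."""
    S = np.cov(stage3_sample, rowvar=False, ddof=1)
    return sem.fit_ml(stage3_spec, S, stage3_sample.shape[0], seed=0)
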