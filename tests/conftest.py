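import numpy as np
import pytest

from riskscape import GeneratorConfig, TrueParameters, generate_cohort


@pytest.fixture(scope="session")
def default_truth():
    return TrueParameters()


@pytest.fixture(scope="session")
def cohort600():
    """A study-sized cohort under default (MAR) conditions."""
    return generate_cohort(GeneratorConfig(n_participants=600, seed=7))


@pytest.fixture(scope="session")
def cohort600_latent():
    """Oracle cohort (MCAR attrition) with its latent generating values."""
    cfg = GeneratorConfig(n_participants=600, seed=21,
                          attrition_mechanism="MCAR")
    return generate_cohort(cfg, TrueParameters(), return_latent=True)


@pytest.fixture(scope="session")
def small_complete_cohort():
    """Small cohort with no attrition and no predictor missingness."""
    cfg = GeneratorConfig(n_participants=120, seed=3,
                          retention=(1.0, 1.0),
                          wave3_opportunity_retention=1.0,
                          predictor_missing_rate=0.0)
    return generate_cohort(cfg)


def toy_mvn_data(n=20, p=12, seed=0, missing=0.25):
    """Random MVN data with a random missingness mask (>=1 obs/row)."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, p))
    sigma = A @ A.T / p + np.eye(p)
    mu = rng.standard_normal(p)
    Y = rng.multivariate_normal(mu, sigma, size=n)
    mask = rng.random((n, p)) < missing
    for i in range(n):  # keep at least one observed cell per row
        if mask[i].all():
            mask[i, rng.integers(p)] = False
    Y[mask] = np.nan
    return Y, mu, sigma
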