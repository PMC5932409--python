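import numpy as np
import pytest

from lgcpower import GrowthParams, StudyDesign, implied_moments


@pytest.fixture
def annual_design():
    """Five annual occasions over four years — the measurement-density scenario."""
    return StudyDesign([0.0, 1.0, 2.0, 3.0, 4.0])


@pytest.fixture
def annual_params():
    """var_I=10, var_S=1, var_e=50: low-reliability planning parameters."""
    return GrowthParams(var_intercept=10.0, var_slope=1.0, var_residual=50.0)


def make_exact_sample(design, params, n_subjects, seed=0):
    """An N x M sample whose ML mean and covariance EQUAL the implied moments.

    Whitens a random draw to exact identity ML covariance and zero mean,
    then colors it with the implied covariance: the true parameters are the
    exact global ML optimum of the resulting sample ("perfect data").
    """
    mom = implied_moments(design, params)
    m = design.n_occasions
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_subjects, m))
    z -= z.mean(axis=0)
    s = z.T @ z / n_subjects
    vals, vecs = np.linalg.eigh(s)
    white = z @ vecs @ np.diag(vals**-0.5) @ vecs.T
    chol = np.linalg.cholesky(mom.covariance)
    return white @ chol.T + mom.mean


@pytest.fixture
def exact_sample_factory():
    return make_exact_sample
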