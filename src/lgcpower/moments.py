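"""Model-implied moments of the linear latent growth curve model.

The observed M-vector per subject has mean mu = Lambda nu and covariance
Sigma = Lambda Psi Lambda' + var_e * I, where Lambda is the M x 2 loading
matrix with a unit column (intercept) and the occasion times (slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StudyDesign
from .params import GrowthParams

__all__ = ["ImpliedMoments", "build_loadings", "implied_moments"]


def build_loadings(design: StudyDesign) -> np.ndarray:
    """M x 2 loading matrix: column of ones, column of occasion times."""
    t = design.times_array
    return np.column_stack([np.ones_like(t), t])


@dataclass(frozen=True)
class ImpliedMoments:
    """Loadings, implied covariance and implied mean of one design x parameter pair."""

    loadings: np.ndarray
    covariance: np.ndarray
    mean: np.ndarray

    def recover_latent_covariance(self, var_residual: float) -> np.ndarray:
        """Invert Sigma = Lambda Psi Lambda' + var_e I for Psi (least squares).

        Exact for M >= 3 model-implied covariances; used as a consistency
        check and for method-of-moments starting values.
        """
        lam = self.loadings
        pinv = np.linalg.solve(lam.T @ lam, lam.T)
        theta = var_residual * np.eye(lam.shape[0])
        return pinv @ (self.covariance - theta) @ pinv.T


def implied_moments(design: StudyDesign, params: GrowthParams) -> ImpliedMoments:
    """Compute Sigma = Lambda Psi Lambda' + var_e I and mu = Lambda nu.

    The diagonal entry at time t is var_I + 2 t cov_IS + t^2 var_S + var_e;
    the off-diagonal entry for times s, t is var_I + (s + t) cov_IS + s t var_S.
    """
    lam = build_loadings(design)
    sigma = lam @ params.psi @ lam.T + params.var_residual * np.eye(design.n_occasions)
    sigma = (sigma + sigma.T) / 2.0  # enforce exact symmetry
    mu = lam @ params.latent_means
    return ImpliedMoments(loadings=lam, covariance=sigma, mean=mu)
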