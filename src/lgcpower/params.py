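"""Population parameters of the linear latent growth curve model.

The LGCM describes repeated measures x_ij of person i at occasion t_j as
x_ij = I_i + S_i * t_j + e_ij, with (I_i, S_i) bivariate normal with mean
(mu_I, mu_S) and covariance Psi = [[var_I, cov_IS], [cov_IS, var_S]], and
homoscedastic, serially uncorrelated residuals e_ij ~ N(0, var_e).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = ["GrowthParams", "PARAM_NAMES"]

#: Canonical parameter ordering used throughout the package.
PARAM_NAMES = (
    "mu_intercept",
    "mu_slope",
    "var_intercept",
    "var_slope",
    "cov_intercept_slope",
    "var_residual",
)

_PSD_TOL = 1e-10


@dataclass(frozen=True, kw_only=True)
class GrowthParams:
    """LGCM population parameters.

    Parameters
    ----------
    mu_intercept, mu_slope
        Latent means (score units; score units per year). Default 0: the
        variance tests considered here are invariant to the mean structure.
    var_intercept
        Between-person variance of the level at time 0 (squared score units).
    var_slope
        Between-person variance of the linear rate of change
        (squared score units per year^2).
    cov_intercept_slope
        Covariance of level and rate of change; default 0.
    var_residual
        Occasion-specific residual variance, homogeneous over time.
    """

    mu_intercept: float = 0.0
    mu_slope: float = 0.0
    var_intercept: float
    var_slope: float = 0.0
    cov_intercept_slope: float = 0.0
    var_residual: float

    def __post_init__(self):
        if self.var_intercept < 0 or self.var_slope < 0 or self.var_residual < 0:
            raise ValueError("variances must be non-negative")
        # Psi must be positive semidefinite
        bound = self.var_intercept * self.var_slope
        if self.cov_intercept_slope**2 > bound + _PSD_TOL * max(1.0, bound):
            raise ValueError(
                "cov_intercept_slope^2 exceeds var_intercept*var_slope: "
                "latent covariance matrix is not positive semidefinite"
            )

    @property
    def psi(self) -> np.ndarray:
        """Latent 2x2 covariance matrix of (intercept, slope)."""
        return np.array(
            [
                [self.var_intercept, self.cov_intercept_slope],
                [self.cov_intercept_slope, self.var_slope],
            ]
        )

    @property
    def latent_means(self) -> np.ndarray:
        return np.array([self.mu_intercept, self.mu_slope])

    @property
    def intercept_slope_correlation(self) -> float:
        denom = np.sqrt(self.var_intercept * self.var_slope)
        if denom == 0:
            return 0.0
        return self.cov_intercept_slope / denom

    def replace(self, **changes) -> "GrowthParams":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "GrowthParams":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def with_correlation(
        cls,
        *,
        var_intercept: float,
        var_slope: float,
        intercept_slope_correlation: float,
        var_residual: float,
        mu_intercept: float = 0.0,
        mu_slope: float = 0.0,
    ) -> "GrowthParams":
        """Construct parameters from a latent correlation instead of a covariance."""
        if not -1.0 <= intercept_slope_correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        cov = intercept_slope_correlation * np.sqrt(var_intercept * var_slope)
        return cls(
            mu_intercept=mu_intercept,
            mu_slope=mu_slope,
            var_intercept=var_intercept,
            var_slope=var_slope,
            cov_intercept_slope=float(cov),
            var_residual=var_residual,
        )
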