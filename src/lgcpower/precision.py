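"""Precision and reliability indices for slope variance in linear LGCMs.

Effective error is the error variance a hypothetical *single direct
measurement* of the latent slope would carry in a power-equivalent minimal
model; its inverse is the precision of the repeated-measures design for
detecting individual differences in change. Under zero intercept-slope
covariance it has the closed form

    sigma_eff^2 = var_e / (sum_j t_j^2 - eta * (sum_j t_j)^2),
    eta = 1 / (M + var_e / var_I) = ICC2 / M,

with ICC2 = var_I / (var_I + var_e / M) the intraclass correlation of M
repeated measures. Scaling slope variance against effective error yields the
effective curve reliability

    ECR = var_S / (var_S + sigma_eff^2),

a standardized effect size coherent with the power of the likelihood-ratio
test of zero slope variance. Growth rate reliability,
GRR = var_S / (var_S + var_e / SST), is the limiting case reached when
ICC2 -> 1, when var_I = 0, or when the occasion times sum to zero (centered
designs); it is coherent with the Wald test instead.

For non-zero intercept-slope covariance no closed form is known; the
generalized ECR inverts the noncentrality of the chosen likelihood-ratio
test (see :func:`generalized_ecr`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy import optimize

from .design import StudyDesign
from .params import GrowthParams

__all__ = [
    "PrecisionSummary",
    "effective_error",
    "icc2",
    "sst",
    "ecr",
    "grr",
    "precision_summary",
    "generalized_ecr",
]


def sst(design: StudyDesign) -> tuple[float, float]:
    """Sum of squared deviations of occasion times about their mean, and the mean.

    Returns ``(SST, t_bar)`` in (years^2, years).
    """
    return design.sst, design.mean_time


def icc2(var_intercept: float, var_residual: float, n_occasions: int) -> float:
    """Intraclass correlation of M repeated measures: var_I/(var_I + var_e/M)."""
    if n_occasions < 1:
        raise ValueError("n_occasions must be >= 1")
    if var_intercept < 0 or var_residual < 0:
        raise ValueError("variances must be non-negative")
    if var_intercept == 0 and var_residual == 0:
        raise ValueError("ICC2 undefined when both variances are zero")
    if var_intercept == 0:
        return 0.0
    return var_intercept / (var_intercept + var_residual / n_occasions)


def _eta(var_intercept: float, var_residual: float, n_occasions: int) -> float:
    # eta = 1/(M + var_e/var_I); defined as 0 by continuity at var_I = 0,
    # matching the ICC2 = 0 limiting case.
    if var_intercept == 0:
        return 0.0
    return 1.0 / (n_occasions + var_residual / var_intercept)


def effective_error(
    design: StudyDesign, var_intercept: float, var_residual: float
) -> float:
    """Effective error of the slope under zero intercept-slope covariance.

    ``var_e / (sum t^2 - eta (sum t)^2)`` — increases with residual and
    intercept variance, decreases as occasions are added or spread out.
    """
    if var_residual <= 0:
        raise ValueError("var_residual must be positive")
    if var_intercept < 0:
        raise ValueError("var_intercept must be non-negative")
    t = design.times_array
    m = design.n_occasions
    eta = _eta(var_intercept, var_residual, m)
    denom = float(np.sum(t**2) - eta * np.sum(t) ** 2)
    if denom <= 0:
        raise ValueError("degenerate design: occasions carry no slope information")
    return var_residual / denom


def ecr(var_slope: float, effective_error: float) -> float:
    """Effective curve reliability var_S/(var_S + sigma_eff^2), in [0, 1]."""
    if var_slope < 0 or effective_error < 0:
        raise ValueError("arguments must be non-negative")
    if var_slope == 0 and effective_error == 0:
        raise ValueError("ECR undefined when slope variance and effective error are both zero")
    return var_slope / (var_slope + effective_error)


def grr(var_slope: float, var_residual: float, sst: float) -> float:
    """Growth rate reliability var_S/(var_S + var_e/SST), in [0, 1].

    Shift-invariant (depends on times only through SST); the Wald-test
    counterpart of ECR.
    """
    if sst <= 0:
        raise ValueError("SST must be positive (all occasions identical?)")
    if var_slope < 0 or var_residual < 0:
        raise ValueError("variances must be non-negative")
    denom = var_slope + var_residual / sst
    if denom == 0:
        raise ValueError("GRR undefined: no slope variance and no residual error")
    return var_slope / denom


@dataclass(frozen=True)
class PrecisionSummary:
    """All precision/reliability indices for one design x parameter pair."""

    effective_error: float   # sigma_eff^2, squared score units
    special_case_error: float  # var_e / SST (the ICC2 -> 1 limit)
    ecr: float
    grr: float
    icc2: float
    eta: float
    sst: float               # years^2
    mean_time: float         # years
    dispersion: float        # SST/(M-1), years^2

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}


def precision_summary(design: StudyDesign, params: GrowthParams) -> PrecisionSummary:
    """Compute every precision index for a design under given population parameters.

    With zero intercept-slope covariance all indices are closed-form. With a
    non-zero covariance, ECR is delegated to :func:`generalized_ecr` (2-df
    generalized test, under which the index stays coherent with power) and
    the effective error is back-solved from it, keeping the summary
    internally consistent: ecr == var_S/(var_S + effective_error) exactly.
    """
    s, tbar = sst(design)
    m = design.n_occasions
    ic = icc2(params.var_intercept, params.var_residual, m)
    eta = _eta(params.var_intercept, params.var_residual, m)
    special = params.var_residual / s
    if params.cov_intercept_slope == 0:
        eff = effective_error(design, params.var_intercept, params.var_residual)
        rel = ecr(params.var_slope, eff)
    else:
        rel = generalized_ecr(design, params, test="generalized_2df")
        if rel >= 1.0:
            raise ValueError("generalized ECR reached 1; effective error undefined")
        eff = params.var_slope * (1.0 - rel) / rel if rel > 0 else np.inf
    return PrecisionSummary(
        effective_error=eff,
        special_case_error=special,
        ecr=rel,
        grr=grr(params.var_slope, params.var_residual, s),
        icc2=ic,
        eta=eta,
        sst=s,
        mean_time=tbar,
        dispersion=design.dispersion,
    )


def _evidence(ecr_value: float) -> float:
    # per-subject noncentrality as a function of ECR (monotone increasing)
    u = 1.0 / (1.0 - ecr_value)
    return u - np.log(u) - 1.0


def generalized_ecr(
    design: StudyDesign,
    params: GrowthParams,
    test: Literal["specific_1df", "generalized_2df"] = "generalized_2df",
    nuisance_policy: Literal["fixed_true", "free"] = "fixed_true",
) -> float:
    """ECR for arbitrary intercept-slope covariance, via noncentrality inversion.

    Computes the per-subject noncentrality f = lambda/N of the chosen
    likelihood-ratio test from the population implied moments (Satorra-Saris
    construction, see :mod:`lgcpower.power`), then returns the unique
    ECR in [0, 1) solving

        f = 1/(1-ECR) - ln(1/(1-ECR)) - 1,

    the per-subject evidence of the minimal power-equivalent model. With
    zero covariance and nuisance parameters fixed at their true values this
    reproduces the closed-form ECR exactly. The free-nuisance policy yields
    a smaller noncentrality, hence a smaller (more conservative) ECR.
    """
    from .power import satorra_saris_lambda  # local import: power depends on this module

    f = satorra_saris_lambda(
        design, params, test=test, nuisance_policy=nuisance_policy, n_subjects=1
    )
    if f <= 0:
        return 0.0
    # _evidence is strictly increasing on [0, 1); bracket then root-find.
    hi = 1.0 - 1e-15
    if f >= _evidence(hi):
        return hi
    sol = optimize.brentq(lambda r: _evidence(r) - f, 0.0, hi, xtol=1e-12, rtol=1e-15)
    return float(sol)
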