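"""Analytic power for likelihood-ratio tests of zero slope variance.

The route is: effective error -> ECR -> noncentrality lambda -> power.
In the minimal power-equivalent model the unrestricted implied "covariance"
is the scalar var_S + sigma_eff^2 and the restricted one is sigma_eff^2,
which (with an unrestricted mean structure) gives the noncentrality of the
1-df specific variance test

    lambda = N * [1/(1-ECR) - ln(1/(1-ECR)) - 1].

For arbitrary parameters the same quantity is obtained directly from the
population implied moments: fit the restricted model to the moments implied
under the alternative and take N times the minimized maximum-likelihood
discrepancy (the Satorra-Saris construction). Power is the survival
function of the noncentral chi-square at the null critical value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import optimize, stats

from .design import StudyDesign
from .moments import implied_moments
from .params import GrowthParams
from .precision import ecr as _ecr_index
from .precision import effective_error as _effective_error

__all__ = [
    "TestSpec",
    "PowerEstimate",
    "TEST_DF",
    "noncentrality_from_ecr",
    "noncentrality_approx",
    "ml_discrepancy",
    "satorra_saris_lambda",
    "critical_value",
    "power_from_lambda",
    "analytic_power",
]

TestKind = Literal["specific_1df", "generalized_2df", "wald"]
NullReference = Literal["plain_chisq", "boundary_mixture"]

#: degrees of freedom of each likelihood-ratio test kind
TEST_DF = {"specific_1df": 1, "generalized_2df": 2, "wald": 1}


@dataclass(frozen=True)
class TestSpec:
    """A hypothesis test of zero slope variance.

    ``specific_1df`` assumes zero intercept-slope covariance in both nested
    models; ``generalized_2df`` frees slope variance and covariance jointly;
    ``wald`` is the estimated slope variance over its standard error.
    """

    kind: TestKind = "specific_1df"
    alpha: float = 0.05
    null_reference: NullReference = "plain_chisq"

    def __post_init__(self):
        if self.kind not in TEST_DF:
            raise ValueError(f"unknown test kind {self.kind!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def df(self) -> int:
        return TEST_DF[self.kind]


@dataclass(frozen=True)
class PowerEstimate:
    """Power of a slope-variance test for one design x parameter x N triple."""

    power: float
    n_subjects: int
    alpha: float
    df: int
    method: Literal["analytic", "monte_carlo"]
    noncentrality: Optional[float] = None
    nrep: Optional[int] = None
    mc_standard_error: Optional[float] = None
    n_nonconverged: int = 0

    def to_dict(self) -> dict:
        d = {
            "power": float(self.power),
            "n_subjects": int(self.n_subjects),
            "alpha": float(self.alpha),
            "df": int(self.df),
            "method": self.method,
        }
        if self.noncentrality is not None:
            d["noncentrality"] = float(self.noncentrality)
        if self.nrep is not None:
            d["nrep"] = int(self.nrep)
            d["mc_standard_error"] = float(self.mc_standard_error)
            d["n_nonconverged"] = int(self.n_nonconverged)
        return d


def noncentrality_from_ecr(ecr: float, n_subjects: float) -> float:
    """Noncentrality N*[1/(1-ECR) - ln(1/(1-ECR)) - 1]; increasing, convex in ECR."""
    if not 0.0 <= ecr < 1.0:
        raise ValueError("ECR must lie in [0, 1)")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    u = 1.0 / (1.0 - ecr)
    return float(n_subjects * (u - np.log(u) - 1.0))


def noncentrality_approx(ecr: float, n_subjects: float) -> float:
    """Printed small-ECR approximation N*ECR^2/(1-ECR).

    Provided verbatim for reference only; it is not consistent with the
    Taylor expansion of the exact expression (whose leading term is
    N*ECR^2/2) and is never used internally.
    """
    if not 0.0 <= ecr < 1.0:
        raise ValueError("ECR must lie in [0, 1)")
    return float(n_subjects * ecr**2 / (1.0 - ecr))


def ml_discrepancy(sigma_model: np.ndarray, sigma_pop: np.ndarray) -> float:
    """ML discrepancy F = ln|S_m| + tr(S_p S_m^-1) - ln|S_p| - M.

    Unit-consistent with -2LL differences: N*F is the expected LR statistic
    noncentrality when ``sigma_model`` is the restricted implied covariance
    and ``sigma_pop`` the population one (means unrestricted).
    """
    m = sigma_pop.shape[0]
    sign_m, logdet_m = np.linalg.slogdet(sigma_model)
    sign_p, logdet_p = np.linalg.slogdet(sigma_pop)
    if sign_m <= 0 or sign_p <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    trace = float(np.trace(np.linalg.solve(sigma_model, sigma_pop)))
    return float(logdet_m + trace - logdet_p - m)


def satorra_saris_lambda(
    design: StudyDesign,
    params: GrowthParams,
    test: TestKind | TestSpec = "specific_1df",
    nuisance_policy: Literal["fixed_true", "free"] = "fixed_true",
    n_subjects: float = 1.0,
) -> float:
    """LR-test noncentrality from the population implied moments.

    The restricted model fixes var_S = 0 and cov_IS = 0 (with intercept
    variance and residual variance as nuisance parameters); the unrestricted
    reference is the model the test estimates under the alternative: for the
    2-df generalized test the full model (zero discrepancy), for the 1-df
    specific test the model with cov_IS constrained to 0 (which misfits if
    the true covariance is non-zero). lambda = N * (F_restricted - F_unrestricted),
    evaluated with the mean structure unrestricted, so only the covariance
    part contributes.

    ``nuisance_policy='fixed_true'`` holds nuisance parameters at their true
    values (the power-equivalence convention; ECR-coherent).
    ``'free'`` minimizes each discrepancy over the nuisance parameters,
    yielding a smaller, more conservative lambda.
    """
    kind = test.kind if isinstance(test, TestSpec) else test
    if kind == "wald":
        raise ValueError("the Satorra-Saris construction applies to LR tests only")
    if design.n_occasions < 3:
        raise ValueError("lambda computation requires at least 3 occasions")
    sigma_pop = implied_moments(design, params).covariance

    def fit_f(free_names: tuple[str, ...], fixed: dict[str, float]) -> float:
        """Minimized discrepancy of the sub-model over ``free_names``."""
        base = {
            "var_intercept": params.var_intercept,
            "var_slope": params.var_slope,
            "cov_intercept_slope": params.cov_intercept_slope,
            "var_residual": params.var_residual,
        }
        base.update(fixed)
        lam_mat = np.column_stack([np.ones(design.n_occasions), design.times_array])

        def objective(theta):
            vals = dict(base)
            vals.update(dict(zip(free_names, theta)))
            psi = np.array(
                [
                    [vals["var_intercept"], vals["cov_intercept_slope"]],
                    [vals["cov_intercept_slope"], vals["var_slope"]],
                ]
            )
            sigma = lam_mat @ psi @ lam_mat.T + vals["var_residual"] * np.eye(
                design.n_occasions
            )
            try:
                return ml_discrepancy(sigma, sigma_pop)
            except np.linalg.LinAlgError:
                return 1e12

        if not free_names:
            return objective(())
        x0 = np.array([base[name] for name in free_names])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        if not res.success:
            raise RuntimeError(f"inner restricted-model fit failed: {res.message}")
        return float(res.fun)

    restricted_fixed = {"var_slope": 0.0, "cov_intercept_slope": 0.0}
    if nuisance_policy == "fixed_true":
        f_res = fit_f((), restricted_fixed)
        if kind == "specific_1df":
            f_unres = fit_f((), {"cov_intercept_slope": 0.0})
        else:
            f_unres = 0.0
    elif nuisance_policy == "free":
        f_res = fit_f(("var_intercept", "var_residual"), restricted_fixed)
        if kind == "specific_1df":
            f_unres = fit_f(
                ("var_intercept", "var_slope", "var_residual"),
                {"cov_intercept_slope": 0.0},
            )
        else:
            f_unres = 0.0
    else:
        raise ValueError(f"unknown nuisance policy {nuisance_policy!r}")
    return float(n_subjects) * max(f_res - f_unres, 0.0)


def critical_value(df: int, alpha: float, null_reference: NullReference = "plain_chisq") -> float:
    """Critical value of the null reference distribution.

    ``plain_chisq``: central chi-square with ``df`` degrees of freedom.
    ``boundary_mixture``: the 50:50 mixture arising when variances are
    restricted to the boundary — chi2(0):chi2(1) for df=1 and
    chi2(1):chi2(2) for df=2.
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    if null_reference == "plain_chisq":
        return float(stats.chi2.ppf(1.0 - alpha, df))
    if null_reference == "boundary_mixture":
        if df == 1:
            # 0.5*P(chi2_1 > c) = alpha  (point mass at zero contributes nothing)
            return float(stats.chi2.ppf(1.0 - 2.0 * alpha, 1))
        sol = optimize.brentq(
            lambda c: 0.5 * stats.chi2.sf(c, 1) + 0.5 * stats.chi2.sf(c, 2) - alpha,
            1e-9, 100.0, xtol=1e-12,
        )
        return float(sol)
    raise ValueError(f"unknown null reference {null_reference!r}")


def power_from_lambda(
    lam: float,
    df: int,
    alpha: float = 0.05,
    null_reference: NullReference = "plain_chisq",
) -> float:
    """P(noncentral chi2(df, lambda) > critical value); equals alpha at lambda = 0."""
    if lam < 0:
        raise ValueError("noncentrality must be non-negative")
    crit = critical_value(df, alpha, null_reference)
    if lam == 0:
        return float(stats.chi2.sf(crit, df))
    return float(stats.ncx2.sf(crit, df, lam))


def analytic_power(
    design: StudyDesign,
    params: GrowthParams,
    n_subjects: Optional[int] = None,
    test: TestKind | TestSpec = "specific_1df",
    alpha: float = 0.05,
    null_reference: NullReference = "plain_chisq",
    nuisance_policy: Literal["fixed_true", "free"] = "fixed_true",
) -> PowerEstimate:
    """Analytic power chain: effective error -> ECR -> lambda -> power.

    With zero intercept-slope covariance and the 1-df test the closed forms
    are used; otherwise lambda comes from :func:`satorra_saris_lambda`.
    Because nuisance parameters are held fixed (power-equivalence
    convention), the value typically overestimates the power of a fully
    freely estimated analysis; a Monte Carlo run gives the realistic figure.
    """
    spec = test if isinstance(test, TestSpec) else TestSpec(kind=test, alpha=alpha,
                                                            null_reference=null_reference)
    n = int(n_subjects) if n_subjects is not None else design.require_n()
    if spec.kind == "wald":
        raise ValueError("analytic power is defined for the LR tests; "
                         "use mc_power for the Wald test")
    if params.cov_intercept_slope == 0 and spec.kind == "specific_1df" \
            and nuisance_policy == "fixed_true":
        eff = _effective_error(design, params.var_intercept, params.var_residual)
        rel = _ecr_index(params.var_slope, eff)
        lam = noncentrality_from_ecr(rel, n)
    else:
        lam = satorra_saris_lambda(
            design, params, test=spec.kind,
            nuisance_policy=nuisance_policy, n_subjects=n,
        )
    pw = power_from_lambda(lam, spec.df, spec.alpha, spec.null_reference)
    return PowerEstimate(
        power=pw, n_subjects=n, alpha=spec.alpha, df=spec.df,
        method="analytic", noncentrality=lam,
    )
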