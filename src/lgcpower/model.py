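"""Maximum-likelihood estimation of the linear LGCM and the slope-variance tests.

:class:`LatentGrowthCurve` is a statsmodels-style model object built from an
N x M table of repeated measures; :meth:`LatentGrowthCurve.fit` minimizes the
multivariate-normal ML discrepancy between the sample moments and the
model-implied moments and returns an :class:`LGCMResults` carrying estimates,
standard errors (observed information), -2 log-likelihood and a summary table.

Three tests of zero slope variance are provided on top:

* ``specific_1df`` LR test — both nested models assume zero intercept-slope
  covariance; only the slope variance is tested.
* ``generalized_2df`` LR test — slope variance and intercept-slope covariance
  are tested jointly.
* Wald test — estimated slope variance over its standard error, one-sided
  standard-normal reference.

Variance parameters are estimated unconstrained by default (they may go
negative) and LR statistics are referred to plain chi-square critical values;
a constrained mode (variances bounded at zero) is available for sensitivity
analysis together with the boundary-mixture reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.iolib.table import SimpleTable
from statsmodels.tools.numdiff import approx_hess3

from .design import StudyDesign
from .moments import build_loadings
from .params import GrowthParams, PARAM_NAMES
from .sampling import LongitudinalSample

__all__ = ["LatentGrowthCurve", "LGCMResults", "TestResult", "lr_test", "wald_test"]

_COV_NAMES = ("var_intercept", "var_slope", "cov_intercept_slope", "var_residual")
_MEAN_NAMES = ("mu_intercept", "mu_slope")
_LN_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one slope-variance test."""

    statistic: float
    df: int
    p_value: float
    kind: str
    restricted: Optional["LGCMResults"] = None
    unrestricted: Optional["LGCMResults"] = None
    fit: Optional["LGCMResults"] = None  # the single fit behind a Wald test

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"TestResult(kind={self.kind!r}, statistic={self.statistic:.4f}, "
                f"df={self.df}, p_value={self.p_value:.4g})")


class LatentGrowthCurve:
    """Linear latent growth curve model for complete balanced panel data.

    Parameters
    ----------
    endog
        N x M array of observed scores, one row per subject, one column per
        occasion.
    times
        The M occasion times (years), or a :class:`StudyDesign`.

    Examples
    --------
    >>> model = LatentGrowthCurve(values, times=[0, 1, 2, 3, 4])
    >>> res = model.fit()
    >>> res.params.var_slope, res.bse["var_slope"]
    """

    def __init__(self, endog, times):
        design = times if isinstance(times, StudyDesign) else StudyDesign(times)
        endog = np.asarray(endog, dtype=float)
        if endog.ndim != 2:
            raise ValueError("endog must be 2-dimensional (subjects x occasions)")
        if design.n_occasions < 3:
            raise ValueError("model fitting requires at least 3 occasions "
                             "(identification)")
        self.sample = LongitudinalSample(values=endog, design=design.with_n(endog.shape[0]))
        self.design = self.sample.design
        self.loadings = build_loadings(design)
        # sufficient statistics (ML convention: covariance divides by N)
        self._xbar = self.sample.mean_vector()
        self._s = self.sample.covariance()
        sign, self._logdet_s = np.linalg.slogdet(self._s)
        if sign <= 0:
            raise ValueError("sample covariance is singular; N too small "
                             "or degenerate data")

    # ---------------------------------------------------------------- io
    @classmethod
    def from_sample(cls, sample: LongitudinalSample) -> "LatentGrowthCurve":
        return cls(sample.values, sample.design)

    @classmethod
    def from_wide(cls, data: pd.DataFrame, times: Optional[Sequence[float]] = None
                  ) -> "LatentGrowthCurve":
        """Build from a wide data frame (columns ``id, t<time1>, ..., t<timeM>``).

        When ``times`` is not given, occasion times are parsed from the
        column names.
        """
        cols = [c for c in data.columns if c != "id"]
        if times is None:
            try:
                times = [float(str(c).lstrip("t")) for c in cols]
            except ValueError as exc:
                raise ValueError(
                    "cannot parse occasion times from column names; "
                    "pass times= explicitly"
                ) from exc
        return cls(data[cols].to_numpy(dtype=float), times)

    @classmethod
    def from_long(cls, data: pd.DataFrame, id_col: str = "id",
                  time_col: str = "time", value_col: str = "value"
                  ) -> "LatentGrowthCurve":
        """Build from a long data frame (one row per observation).

        Every subject must be observed on the same occasion grid (balanced,
        complete data).
        """
        wide = data.pivot(index=id_col, columns=time_col, values=value_col)
        if wide.isna().any().any():
            raise ValueError("incomplete data: every subject must be measured "
                             "at every occasion")
        times = [float(t) for t in wide.columns]
        return cls(wide.to_numpy(dtype=float), times)

    # ------------------------------------------------------------- likelihood
    def _sigma(self, cov: Mapping[str, float]) -> np.ndarray:
        psi = np.array([
            [cov["var_intercept"], cov["cov_intercept_slope"]],
            [cov["cov_intercept_slope"], cov["var_slope"]],
        ])
        return (self.loadings @ psi @ self.loadings.T
                + cov["var_residual"] * np.eye(self.design.n_occasions))

    def _profile_means(self, sigma_inv: np.ndarray) -> np.ndarray:
        """GLS latent means given Sigma (the ML estimate for fixed covariances)."""
        lam = self.loadings
        a = lam.T @ sigma_inv @ lam
        b = lam.T @ sigma_inv @ self._xbar
        return np.linalg.solve(a, b)

    def _discrepancy(self, cov: Mapping[str, float]) -> float:
        """F_ML with the means profiled out; -2LL = N*(F + ln|S| + M + M ln 2pi)."""
        sigma = self._sigma(cov)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        sigma_inv = np.linalg.inv(sigma)
        nu = self._profile_means(sigma_inv)
        d = self._xbar - self.loadings @ nu
        trace = float(np.sum(sigma_inv * self._s))
        quad = float(d @ sigma_inv @ d)
        m = self.design.n_occasions
        return logdet + trace + quad - self._logdet_s - m

    def minus2ll(self, params: GrowthParams) -> float:
        """Exact -2 log-likelihood of the sample at the given parameters."""
        cov = params.to_dict()
        sigma = self._sigma(cov)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        sigma_inv = np.linalg.inv(sigma)
        mu = self.loadings @ params.latent_means
        n, m = self.sample.n_subjects, self.design.n_occasions
        d = self._xbar - mu
        return n * (m * _LN_2PI + logdet + float(np.sum(sigma_inv * self._s))
                    + float(d @ sigma_inv @ d))

    # ------------------------------------------------------------------ start
    def _start_values(self) -> dict[str, float]:
        """Method-of-moments start: per-subject OLS growth coefficients."""
        lam = self.loadings
        pinv = np.linalg.solve(lam.T @ lam, lam.T)
        coefs = self.sample.values @ pinv.T          # N x 2 (intercept, slope)
        resid = self.sample.values - coefs @ lam.T
        n, m = self.sample.n_subjects, self.design.n_occasions
        if m > 2:
            var_e = float(np.sum(resid**2) / (n * (m - 2)))
        else:
            var_e = 1.0
        var_e = max(var_e, 1e-8)
        cov_b = np.cov(coefs, rowvar=False, ddof=1)
        psi0 = cov_b - var_e * np.linalg.inv(lam.T @ lam)
        return {
            "var_intercept": float(psi0[0, 0]),
            "var_slope": float(psi0[1, 1]),
            "cov_intercept_slope": float(psi0[0, 1]),
            "var_residual": var_e,
        }

    # -------------------------------------------------------------------- fit
    def fit(
        self,
        constraints: Optional[Mapping[str, float]] = None,
        start: Optional[Mapping[str, float]] = None,
        constrained: bool = False,
        max_restarts: int = 5,
        compute_bse: bool = True,
    ) -> "LGCMResults":
        """Maximize the likelihood over the free covariance parameters.

        Parameters
        ----------
        constraints
            Mapping of parameter names (from ``var_intercept, var_slope,
            cov_intercept_slope, var_residual, mu_intercept, mu_slope``) to
            fixed values, e.g. ``{"var_slope": 0.0, "cov_intercept_slope": 0.0}``
            for the restricted model of the slope-variance tests.
        start
            Optional override of the method-of-moments starting values.
        constrained
            When True, variance parameters are bounded below at zero
            (boundary estimation); default False estimates them
            unconstrained, matching the plain chi-square reference.
        max_restarts
            Jittered restarts attempted when the optimizer fails before the
            fit is flagged non-convergent.
        compute_bse
            Skip the numerical Hessian when False (Monte Carlo fast path).
        """
        constraints = dict(constraints or {})
        unknown = set(constraints) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown constrained parameters: {sorted(unknown)}")
        mean_fixed = {k: constraints[k] for k in _MEAN_NAMES if k in constraints}
        cov_fixed = {k: float(constraints[k]) for k in _COV_NAMES if k in constraints}
        free = [k for k in _COV_NAMES if k not in cov_fixed]

        start_all = self._start_values()
        if start is not None:
            start_all.update({k: float(v) for k, v in start.items()})
        if constrained:
            for k in ("var_intercept", "var_slope", "var_residual"):
                start_all[k] = max(start_all[k], 0.0)

        def objective(theta):
            cov = dict(cov_fixed)
            cov.update(dict(zip(free, theta)))
            if constrained and (
                cov["var_intercept"] < 0 or cov["var_slope"] < 0
                or cov["var_residual"] < 0
            ):
                return np.inf
            f = self._discrepancy(cov)
            return f if np.isfinite(f) else 1e12

        x0 = np.array([start_all[k] for k in free])
        best = None
        rng = np.random.default_rng(0)
        converged = False
        n_restarts = 0
        if free:
            for attempt in range(max_restarts + 1):
                xs = x0 if attempt == 0 else x0 * (1 + 0.2 * rng.standard_normal(len(free))) \
                    + 0.05 * rng.standard_normal(len(free))
                res = optimize.minimize(
                    objective, xs, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12,
                             "maxiter": 2000 * len(free), "maxfev": 2000 * len(free)},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
                if res.success and np.isfinite(res.fun):
                    converged = True
                    if res.fun <= best.fun + 1e-10:
                        best = res
                    break
                n_restarts += 1
            theta_hat = best.x
        else:
            converged = True
            theta_hat = np.empty(0)

        cov_hat = dict(cov_fixed)
        cov_hat.update(dict(zip(free, theta_hat)))
        sigma = self._sigma(cov_hat)
        try:
            sigma_inv = np.linalg.inv(sigma)
            nu_hat = self._profile_means(sigma_inv)
        except np.linalg.LinAlgError:
            converged = False
            nu_hat = np.array([np.nan, np.nan])
        est = {
            "mu_intercept": mean_fixed.get("mu_intercept", float(nu_hat[0])),
            "mu_slope": mean_fixed.get("mu_slope", float(nu_hat[1])),
            **cov_hat,
        }
        if mean_fixed:
            # re-profile with any fixed means honored
            est["mu_intercept"] = float(mean_fixed.get("mu_intercept", est["mu_intercept"]))
            est["mu_slope"] = float(mean_fixed.get("mu_slope", est["mu_slope"]))

        params_hat = _as_growth_params(est)
        m2ll = self.minus2ll(params_hat) if converged else np.inf
        free_names = [k for k in _MEAN_NAMES if k not in mean_fixed] + free
        bse = {name: np.nan for name in PARAM_NAMES}
        if compute_bse and converged and free_names:
            bse.update(self._standard_errors(est, free_names))
        return LGCMResults(
            model=self,
            params=params_hat,
            bse=bse,
            minus2ll=float(m2ll),
            converged=bool(converged and np.isfinite(m2ll)),
            constraints={**mean_fixed, **cov_fixed},
            n_subjects=self.sample.n_subjects,
            n_free=len(free_names),
            n_restarts=n_restarts,
        )

    def _standard_errors(self, est: Mapping[str, float], free_names: Sequence[str]
                         ) -> dict[str, float]:
        """Observed-information SEs: invert half the Hessian of -2LL."""
        def m2ll_vec(theta):
            vals = dict(est)
            vals.update(dict(zip(free_names, theta)))
            return self.minus2ll(_as_growth_params(vals, validate=False))

        x = np.array([est[k] for k in free_names])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess3(x, m2ll_vec)
        out = {}
        try:
            cov = 2.0 * np.linalg.inv(hess)
            diag = np.diag(cov)
            for name, v in zip(free_names, diag):
                out[name] = float(np.sqrt(v)) if v > 0 else np.nan
        except np.linalg.LinAlgError:
            for name in free_names:
                out[name] = np.nan
        return out


def _as_growth_params(vals: Mapping[str, float], validate: bool = True) -> GrowthParams:
    """Build GrowthParams, optionally bypassing PSD/positivity validation.

    Unconstrained ML estimates may legitimately leave the parameter space
    (negative variance estimates); results objects still need to carry them.
    """
    if validate:
        try:
            return GrowthParams(**{k: float(vals[k]) for k in PARAM_NAMES})
        except ValueError:
            pass
    obj = object.__new__(GrowthParams)
    for k in PARAM_NAMES:
        object.__setattr__(obj, k, float(vals[k]))
    return obj


@dataclass
class LGCMResults:
    """Fitted LGCM: estimates, uncertainties and fit statistics."""

    model: LatentGrowthCurve
    params: GrowthParams
    bse: dict[str, float]
    minus2ll: float
    converged: bool
    constraints: dict[str, float]
    n_subjects: int
    n_free: int
    n_restarts: int = 0

    @property
    def df_model(self) -> int:
        return self.n_free

    def estimate(self, name: str) -> float:
        return float(getattr(self.params, name))

    def summary(self) -> SimpleTable:
        """Estimation summary table (statsmodels SimpleTable)."""
        rows = []
        for name in PARAM_NAMES:
            fixed = name in self.constraints
            se = self.bse.get(name, np.nan)
            rows.append([
                name,
                f"{self.estimate(name):.4f}",
                "(fixed)" if fixed else (f"{se:.4f}" if np.isfinite(se) else "--"),
            ])
        title = (f"Linear latent growth curve model (N={self.n_subjects}, "
                 f"M={self.model.design.n_occasions}, "
                 f"-2LL={self.minus2ll:.3f}, "
                 f"converged={self.converged})")
        return SimpleTable(rows, headers=["parameter", "estimate", "std err"],
                           title=title)

    def wald_test_slope_variance(self) -> TestResult:
        return wald_test(self)


def lr_test(
    sample: LongitudinalSample | LatentGrowthCurve,
    kind: str = "specific_1df",
    constrained: bool = False,
) -> TestResult:
    """Likelihood-ratio test of zero slope variance.

    ``specific_1df`` compares {var_S=0, cov_IS=0} against {cov_IS=0, var_S
    free}; ``generalized_2df`` compares {var_S=0, cov_IS=0} against the model
    with all three latent (co)variances free. The statistic is the -2LL
    difference, clipped at zero (a warning is emitted if clipping exceeds
    numerical noise).
    """
    model = sample if isinstance(sample, LatentGrowthCurve) \
        else LatentGrowthCurve.from_sample(sample)
    if kind not in ("specific_1df", "generalized_2df"):
        raise ValueError(f"unknown LR test kind {kind!r}")
    restricted = model.fit(
        constraints={"var_slope": 0.0, "cov_intercept_slope": 0.0},
        constrained=constrained, compute_bse=False,
    )
    un_constraints = {"cov_intercept_slope": 0.0} if kind == "specific_1df" else {}
    unrestricted = model.fit(constraints=un_constraints, constrained=constrained,
                             compute_bse=False)
    if not (restricted.converged and unrestricted.converged):
        raise RuntimeError("LR test aborted: a member fit did not converge")
    stat = restricted.minus2ll - unrestricted.minus2ll
    if stat < -1e-6:
        warnings.warn(
            f"negative LR statistic {stat:.3g} clipped to 0 "
            "(restricted fit beat the unrestricted one)",
            RuntimeWarning,
        )
    stat = max(stat, 0.0)
    df = 1 if kind == "specific_1df" else 2
    return TestResult(
        statistic=float(stat), df=df, p_value=float(stats.chi2.sf(stat, df)),
        kind=kind, restricted=restricted, unrestricted=unrestricted,
    )


def wald_test(
    fit: LGCMResults | LongitudinalSample | LatentGrowthCurve,
    assume_zero_covariance: bool = False,
) -> TestResult:
    """Wald test: estimated slope variance over its SE, one-sided normal reference.

    Accepts raw data — in which case the full estimated model is fitted
    first (all latent (co)variances free; set ``assume_zero_covariance`` to
    fix cov_IS at 0 instead) — or an already fitted results object with a
    free slope variance. Computed from the full solution, the test ignores
    intercept variance (its power is governed by GRR, approximately flat in
    ICC2).
    """
    if not isinstance(fit, LGCMResults):
        model = fit if isinstance(fit, LatentGrowthCurve) \
            else LatentGrowthCurve.from_sample(fit)
        constraints = {"cov_intercept_slope": 0.0} if assume_zero_covariance else None
        fit = model.fit(constraints=constraints)
    if not fit.converged:
        raise RuntimeError("Wald test aborted: fit did not converge")
    se = fit.bse.get("var_slope", np.nan)
    if not np.isfinite(se) or se <= 0:
        raise RuntimeError("Wald test undefined: slope-variance SE unavailable "
                           "(singular information matrix?)")
    stat = fit.estimate("var_slope") / se
    return TestResult(
        statistic=float(stat), df=1, p_value=float(stats.norm.sf(stat)),
        kind="wald", fit=fit,
    )
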